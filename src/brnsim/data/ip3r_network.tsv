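source	target	sign
# IP3R calcium-signalling regulatory network (reconstructed fixture).
# Each edge is annotated with the supporting observation; amend here, not in code.
Stimulus	IP3R	activation
# Stimulus: ligand (IP3) binding assumed prior to simulation; drives IP3R in every scenario.
Inhibitor	IP3R	inhibition
# Pharmacological inhibitor abolishes the IP3R calcium pool.
IP3R	Ca2+	activation
# IP3R is the ER calcium-release channel: central node driving Ca2+ influx.
Ca2+	CALM	activation
# Calcium binds calmodulin.
CALM	CAMK-II	activation
# Ca2+/calmodulin activates CaM-kinase II.
CAMK-II	Proliferation	activation
# CaMK pathway drives cell-cycle progression.
CAMK-II	Migration	activation
# CaMK pathway drives cell migration.
Ca2+	CaN	activation
# Calcium activates calcineurin.
CaN	NFAT	activation
# Calcineurin dephosphorylates NFAT, enabling nuclear translocation.
NFAT	Proliferation	activation
# NFAT pathway pushes the cell into S phase.
Ca2+	Bcl-2	activation
# Anti-apoptotic Bcl-2 rises with the calcium/proliferative programme (hyperactive in cancer).
Ca2+	BAD	inhibition
# Adequate Ca2+ signalling keeps pro-apoptotic BAD phosphorylated/inactive.
Bcl-2	BAD	inhibition
# Bcl-2 sequesters BAD.
BAD	BAX	activation
# Active BAD neutralises Bcl-2/Bcl-XL, releasing BAX.
Bcl-2	BAX	inhibition
# Bcl-2 restrains BAX.
BAX	MOMP	activation
# BAX is the effector of mitochondrial outer-membrane permeabilization.
Bcl-2	MOMP	inhibition
# Bcl-2 guards the mitochondrial outer membrane.
MOMP	Cyto.C	activation
# MOMP releases cytochrome c into the cytosol.
Cyto.C	Cyto.C	activation
# Released cytochrome c is not re-sequestered: irreversible commitment (latch).
Cyto.C	Apoptosis	activation
# Cytosolic cytochrome c nucleates the apoptosome; caspase cascade -> apoptosis.
Apoptosis	Proliferation	inhibition
# A dying cell stops proliferating.
Apoptosis	Migration	inhibition
# A dying cell stops migrating.
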