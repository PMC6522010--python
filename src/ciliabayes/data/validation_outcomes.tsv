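# Experimental validation outcomes for the 36 candidate genes tested.
# assay_class: which family of assays the gene was tested with
#   phenotype    = C. elegans roaming / dye-filling, zebrafish morphants
#   localization = eCFP fusions, immunofluorescence (lung epithelium,
#                  hTERT-RPE1, mouse retina)
# outcome: final binary call (ciliary phenotype and/or localization observed)
gene	rank	assay_class	outcome
C20orf26	38	localization	yes
EML1	50	phenotype	no
RIBC2	52	localization	yes
ARMC3	72	localization	yes
SYNE1	80	phenotype	no
EFHC2	88	phenotype	no
CFAP20	96	localization	yes
MAGI2	116	phenotype	yes
SRGAP3	117	phenotype	yes
FAM65B	119	phenotype	no
CCDC113	141	localization	yes
NBEA	170	phenotype	yes
CYB5D1	184	localization	yes
C6orf165	186	localization	yes
DMD	190	phenotype	yes
PPP5C	198	phenotype	no
MYO5B	202	phenotype	no
RALGAPA1	218	phenotype	no
CCDC147	232	localization	yes
C12orf10	243	phenotype	no
C15orf27	257	localization	yes
PLCB4	264	phenotype	yes
ENAH	274	phenotype	yes
EFCAB7	278	phenotype	yes
IQCA1	305	localization	no
HIPK1	306	phenotype	yes
TTC18	319	phenotype	yes
SLC22A4	337	phenotype	no
TSSC1	341	phenotype	no
IPO5	347	localization	yes
HSPAL1	348	localization	yes
VPS35	349	phenotype	yes
SKP1	359	phenotype	no
TEKT1	379	localization	yes
RAB36	395	phenotype	yes
OSCP1	402	phenotype	yes
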