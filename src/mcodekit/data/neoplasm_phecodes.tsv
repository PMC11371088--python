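phecode	label	tcga
145	Cancer of head and neck	HNSC
150	Cancer of esophagus	ESCA
151	Cancer of stomach	STAD
153	Colorectal cancer	COAD
153.3	Cancer of rectum	READ
155	Cancer of liver	LIHC
155.1	Cancer of bile duct	CHOL
157	Pancreatic cancer	PAAD
163	Malignant mesothelioma	MESO
164	Cancer of thymus	THYM
165.1	Cancer of bronchus; lung adenocarcinoma	LUAD
165.2	Cancer of bronchus; lung squamous cell	LUSC
170	Sarcoma of bone and soft tissue	SARC
172.11	Melanoma of skin	SKCM
174.1	Breast cancer	BRCA
180	Cervical cancer	CESC
182	Endometrial cancer	UCEC
182.6	Uterine carcinosarcoma	UCS
184	Ovarian cancer	OV
185	Prostate cancer	PRAD
187	Testicular cancer	TGCT
189.11	Renal clear cell carcinoma	KIRC
189.12	Renal papillary cell carcinoma	KIRP
189.13	Renal chromophobe carcinoma	KICH
189.2	Cancer of bladder	BLCA
190	Uveal melanoma	UVM
191	Lower grade glioma	LGG
191.11	Glioblastoma	GBM
193	Thyroid cancer	THCA
194	Adrenocortical carcinoma	ACC
194.1	Pheochromocytoma and paraganglioma	PCPG
202.2	Diffuse large B-cell lymphoma	DLBC
204.1	Acute myeloid leukemia	LAML
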