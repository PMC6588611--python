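# Reference cohort per-cancer-type counts (patients, carriers as printed).
# The printed per-type carrier counts sum to 109 while the printed carrier
# total is 113; the fixture builder redistributes the 4 unallocated
# carriers to types whose fractions are not individually reported.
cancer_type	patients	carriers
Colorectal cancer	141	27
Breast cancer	85	16
Bile duct cancer	47	8
Pancreatic cancer	43	7
NSCLC	33	4
Prostate cancer	26	3
Ovarian cancer	23	7
Urothelial cancer	20	5
Gastric cancer	20	1
Cervical cancer	18	1
Others	17	1
CUP	16	4
Sarcoma	14	3
Head and neck cancer	14	2
Neuroendocrine cancer	13	1
Malignant Mesothelioma	12	7
Melanoma	12	2
Esophageal cancer	11	2
SCLC	11	0
Hepatocellular cancer	10	2
Adrenocortical cancer	8	0
Endometrial cancer	8	1
Thymoma	8	1
Renal cell carcinoma	6	2
Adenoid cystic carcinoma	5	1
Myoepithelial carcinoma	4	0
Glioblastoma	4	0
Anogenital cancer	3	0
Germ cell cancer	2	0
Vulvovaginal cancer	2	1
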