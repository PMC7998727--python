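cancer_type	deep_deletion	shallow_deletion	diploid	gain	amplification
Ovarian Epithelial Tumor	0.34%	29.15%	26.10%	36.27%	8.14%
Endometrial Carcinoma	-	12.13%	69.67%	14.90%	3.29%
Adrenocortical Carcinoma	-	1.32%	34.21%	61.84%	2.63%
Pleural Mesothelioma	-	8.05%	73.56%	16.09%	2.30%
Esophageal Squamous Cell Carcinoma	-	34.04%	44.68%	19.15%	2.13%
Cervical Squamous Cell Carcinoma	0.41%	26.23%	57.79%	13.52%	2.05%
Diffuse Glioma	0.20%	3.33%	73.92%	20.78%	1.76%
Sarcoma	-	10.36%	50.20%	37.85%	1.59%
Invasive Breast Carcinoma	0.09%	21.25%	60.11%	17.23%	1.31%
Ocular Melanoma	-	3.75%	92.50%	2.50%	1.25%
Thymic Epithelial Tumor	-	2.52%	94.12%	2.52%	0.84%
Esophagogastric Adenocarcinoma	0.62%	33.40%	57.73%	7.42%	0.82%
Head and Neck Squamous Cell Carcinoma	0.20%	19.45%	66.99%	12.57%	0.79%
Glioblastoma	-	8.11%	58.11%	33.11%	0.68%
Non-Small Cell Lung Cancer	0.30%	44.10%	43.39%	11.71%	0.50%
Bladder Urothelial Carcinoma	-	29.21%	53.71%	16.58%	0.50%
Prostate Adenocarcinoma	0.20%	5.74%	92.21%	1.64%	0.20%
Cervical Adenocarcinoma	2.17%	26.09%	65.22%	6.52%	-
Cholangiocarcinoma	-	13.89%	72.22%	13.89%	-
Colorectal Adenocarcinoma	0.51%	11.02%	71.86%	16.61%	-
Encapsulated Glioma	-	-	100.00%	-	-
Fibrolamellar Carcinoma	-	-	100.00%	-	-
Hepatocellular Carcinoma	0.28%	21.51%	64.25%	13.97%	-
Leukemia	-	1.81%	95.18%	3.01%	-
Mature B-Cell Neoplasms	-	2.08%	91.67%	6.25%	-
Melanoma	-	22.62%	61.31%	16.08%	-
Miscellaneous Neuroepithelial Tumor	-	-	96.30%	3.70%	-
Non-Seminomatous Germ Cell Tumor	-	52.33%	33.72%	13.95%	-
Pancreatic Adenocarcinoma	-	14.77%	77.27%	7.95%	-
Pheochromocytoma	-	0.75%	84.33%	14.93%	-
Renal Clear Cell Carcinoma	-	2.17%	88.56%	9.27%	-
Renal Non-Clear Cell Carcinoma	-	5.17%	87.36%	7.47%	-
Seminoma	-	1.59%	55.56%	42.86%	-
Undifferentiated Stomach Adenocarcinoma	-	25.00%	58.33%	16.67%	-
Well-Differentiated Thyroid Cancer	-	1.21%	97.37%	1.41%	-
All Cancer types	0.17%	17.69%	66.83%	14.30%	1.01%
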