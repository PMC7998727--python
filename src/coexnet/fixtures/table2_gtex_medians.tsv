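tissue	RNASEH1	RNASEH2A	RNASEH2B	RNASEH2C
Liver	5.193	3.947	3.878	11.57
Muscle-Skeletal	11.72	5.9535	5.51	9.215
Heart-Left Ventricle	7.251	4.262	8.466	12.71
Pancreas	5.3175	6.44	10.175	11.48
Whole Blood	2.726	7.958	6.471	16.33
Brain-Putamen (basal ganglia)	4.6985	5.5965	7.875	15.635
Brain-Caudate (basal ganglia)	5.1025	6.1935	9.2325	17.175
Brain-Substantia nigra	6.0725	7.4295	8.123	16.355
Brain-Amygdala	5.0275	7.4755	8.2985	17.285
Brain-Hippocampus	5.907	6.655	7.567	18.76
Brain-Anterior cingulate cortex (BA24)	5.921	6.326	9.554	19.13
Brain-Hypothalamus	6.903	7.451	8.639	18.47
Kidney-Cortex	6.303	6.632	6.614	22.18
Brain-Nucleus accumbens (basal ganglia)	6.557	7.162	12.03	20.17
Heart-Atrial Appendage	8.609	5.969	9.644	22.33
Brain-Cortex	5.5355	6.8145	11.095	25.555
Brain-Frontal Cortex (BA9)	7.597	6.766	13.7	23.46
Stomach	8.19	9.396	12.55	24.365
Brain-Spinal cord (cervical c-1)	9.183	13.54	10.54	22.75
Skin-Sun Exposed (Lower leg)	11.62	18.75	10.87	19.18
Skin-Not Sun Exposed (Suprapubic)	10.72	18.3	11.7	19.98
Minor Salivary Gland	10.33	13.21	13.03	24.15
Esophagus-Mucosa	10.58	24.62	11.92	18.2
Colon-Transverse	9.484	12.52	14.885	28.96
Adrenal Gland	10.045	9.7865	12.39	35.965
Adipose-Visceral (Omentum)	12.25	12.14	14.71	32.23
Small Intestine-Terminal Ileum	9.633	14.12	18.32	30.46
Adipose-Subcutaneous	13.845	15.96	16.585	30.145
Lung	12.92	14.51	19.34	30.99
Breast-Mammary Tissue	12.93	16.39	16.65	33.895
Pituitary	8.271	11.02	14.5	52.95
Vagina	12.08	20.33	16.85	39.11
Esophagus-Muscularis	14.91	8.687	22.84	46.885
Artery-Tibial	16.91	8.638	17.8	50.75
Thyroid	12.615	16.935	24.905	43.205
Esophagus-Gastroesophageal Junction	13.75	8.3635	22.05	53.92
Bladder	15.4	15.95	23.68	43.32
Artery-Coronary	13.65	10.5	18.58	56.4
Artery-Aorta	14.63	9.235	17.31	58.05
Prostate	11.11	11.475	20.27	57.625
Nerve-Tibial	15.18	19.24	19.55	48.22
Fallopian Tube	14.57	13.31	25.31	49.21
Colon-Sigmoid	13.24	10	24.46	55.42
Cells-Transformed fibroblasts	29.98	34.04	17.95	25.17
Brain-Cerebellum	9.384	16.21	12.41	70.97
Spleen	10.935	25.695	24.555	49.11
Ovary	12.4	19.46	20.07	59.51
Cervix-Ectocervix	14.765	24.625	23.54	51.435
Brain-Cerebellar Hemisphere	13.325	17.52	14.98	68.75
Cervix-Endocervix	15.15	19	26.62	55
Testis	14.12	49.84	23.42	31.66
Uterus	16.6	21.33	30.43	66.03
Cells-Epstein-Barr virus (EBV)-transformed lymphocytes	27.94	79.945	41.36	32.195
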