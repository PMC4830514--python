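# term	canonical	kind
prostate cancer	prostate cancer	disease
breast cancer	breast cancer	disease
gastric cancer	gastric cancer	disease
gastric cardia carcinoma	gastric cardia carcinoma	disease
CHD	coronary heart disease	disease
coronary heart disease	coronary heart disease	disease
neuroblastoma	neuroblastoma	disease
NSCLC	NSCLC	disease
non-small cell lung cancer	NSCLC	disease
non small cell lung cancer	NSCLC	disease
ovarian cancer	ovarian cancer	disease
oral submucous fibrosis	oral submucous fibrosis	disease
HCC	hepatocellular carcinoma	disease
hepatocellular carcinoma	hepatocellular carcinoma	disease
CHB	chronic hepatitis B	disease
chronic hepatitis B	chronic hepatitis B	disease
B cell lymphoma	B cell lymphoma	disease
brain cancer	brain cancer	disease
germline tumor	germ cell tumor	disease
germ cell tumor	germ cell tumor	disease
colorectal cancer	colorectal cancer	disease
lung cancer	lung cancer	disease
esophageal cancer	esophageal cancer	disease
skin cancer	skin cancer	disease
oral cancer	oral cancer	disease
colon cancer	colon cancer	disease
pancreatic cancer	pancreatic cancer	disease
HNPCC	hereditary non-polyposis colorectal cancer	disease
hereditary non-polyposis colorectal cancer	hereditary non-polyposis colorectal cancer	disease
hereditary nonpolyposis colorectal cancer	hereditary non-polyposis colorectal cancer	disease
phyllodes tumor	phyllodes tumor	disease
malignant phyllodes tumor	phyllodes tumor	disease
ovarian-cancer	ovarian cancer	disease
breast-cancer	breast cancer	disease
bladder cancer	bladder cancer	disease
cervical cancer	cervical cancer	disease
endometrial cancer	endometrial cancer	disease
liver cancer	liver cancer	disease
kidney cancer	kidney cancer	disease
renal cell carcinoma	renal cell carcinoma	disease
thyroid cancer	thyroid cancer	disease
melanoma	melanoma	disease
glioma	glioma	disease
glioblastoma	glioblastoma	disease
astrocytoma	astrocytoma	disease
meningioma	meningioma	disease
medulloblastoma	medulloblastoma	disease
retinoblastoma	retinoblastoma	disease
osteosarcoma	osteosarcoma	disease
Ewing sarcoma	Ewing sarcoma	disease
rhabdomyosarcoma	rhabdomyosarcoma	disease
leukemia	leukemia	disease
acute myeloid leukemia	acute myeloid leukemia	disease
chronic myeloid leukemia	chronic myeloid leukemia	disease
acute lymphoblastic leukemia	acute lymphoblastic leukemia	disease
chronic lymphocytic leukemia	chronic lymphocytic leukemia	disease
lymphoma	lymphoma	disease
Hodgkin lymphoma	Hodgkin lymphoma	disease
non-Hodgkin lymphoma	non-Hodgkin lymphoma	disease
multiple myeloma	multiple myeloma	disease
myelodysplastic syndrome	myelodysplastic syndrome	disease
head and neck cancer	head and neck cancer	disease
nasopharyngeal carcinoma	nasopharyngeal carcinoma	disease
laryngeal cancer	laryngeal cancer	disease
esophageal squamous cell carcinoma	esophageal squamous cell carcinoma	disease
gastric adenocarcinoma	gastric adenocarcinoma	disease
small cell lung cancer	small cell lung cancer	disease
lung adenocarcinoma	lung adenocarcinoma	disease
lung squamous cell carcinoma	lung squamous cell carcinoma	disease
mesothelioma	mesothelioma	disease
gallbladder cancer	gallbladder cancer	disease
cholangiocarcinoma	cholangiocarcinoma	disease
anal cancer	anal cancer	disease
testicular cancer	testicular cancer	disease
squamous cell carcinoma	squamous cell carcinoma	disease
basal cell carcinoma	basal cell carcinoma	disease
neurofibromatosis	neurofibromatosis	disease
tuberous sclerosis	tuberous sclerosis	disease
Li-Fraumeni syndrome	Li-Fraumeni syndrome	disease
Lynch syndrome	Lynch syndrome	disease
Cowden syndrome	Cowden syndrome	disease
familial adenomatous polyposis	familial adenomatous polyposis	disease
Peutz-Jeghers syndrome	Peutz-Jeghers syndrome	disease
ataxia telangiectasia	ataxia telangiectasia	disease
Fanconi anemia	Fanconi anemia	disease
xeroderma pigmentosum	xeroderma pigmentosum	disease
Bloom syndrome	Bloom syndrome	disease
Werner syndrome	Werner syndrome	disease
cystic fibrosis	cystic fibrosis	disease
sickle cell anemia	sickle cell anemia	disease
thalassemia	thalassemia	disease
hemophilia	hemophilia	disease
Duchenne muscular dystrophy	Duchenne muscular dystrophy	disease
spinal muscular atrophy	spinal muscular atrophy	disease
Huntington disease	Huntington disease	disease
Parkinson disease	Parkinson disease	disease
Alzheimer disease	Alzheimer disease	disease
amyotrophic lateral sclerosis	amyotrophic lateral sclerosis	disease
multiple sclerosis	multiple sclerosis	disease
rheumatoid arthritis	rheumatoid arthritis	disease
systemic lupus erythematosus	systemic lupus erythematosus	disease
Crohn disease	Crohn disease	disease
ulcerative colitis	ulcerative colitis	disease
celiac disease	celiac disease	disease
type 2 diabetes	type 2 diabetes	disease
diabetes mellitus	diabetes mellitus	disease
obesity	obesity	disease
hypertension	hypertension	disease
coronary artery disease	coronary artery disease	disease
myocardial infarction	myocardial infarction	disease
atherosclerosis	atherosclerosis	disease
stroke	stroke	disease
thrombosis	thrombosis	disease
venous thromboembolism	venous thromboembolism	disease
asthma	asthma	disease
chronic obstructive pulmonary disease	chronic obstructive pulmonary disease	disease
pulmonary fibrosis	pulmonary fibrosis	disease
osteoporosis	osteoporosis	disease
osteoarthritis	osteoarthritis	disease
psoriasis	psoriasis	disease
atopic dermatitis	atopic dermatitis	disease
vitiligo	vitiligo	disease
endometriosis	endometriosis	disease
polycystic ovary syndrome	polycystic ovary syndrome	disease
preeclampsia	preeclampsia	disease
schizophrenia	schizophrenia	disease
bipolar disorder	bipolar disorder	disease
major depressive disorder	major depressive disorder	disease
autism	autism	disease
epilepsy	epilepsy	disease
migraine	migraine	disease
glaucoma	glaucoma	disease
macular degeneration	macular degeneration	disease
retinitis pigmentosa	retinitis pigmentosa	disease
hearing loss	hearing loss	disease
chronic kidney disease	chronic kidney disease	disease
nephrotic syndrome	nephrotic syndrome	disease
IgA nephropathy	IgA nephropathy	disease
gout	gout	disease
hemochromatosis	hemochromatosis	disease
Wilson disease	Wilson disease	disease
phenylketonuria	phenylketonuria	disease
hypothyroidism	hypothyroidism	disease
hyperthyroidism	hyperthyroidism	disease
Graves disease	Graves disease	disease
Addison disease	Addison disease	disease
periodontitis	periodontitis	disease
tuberculosis	tuberculosis	disease
hepatitis B	hepatitis B	disease
hepatitis C	hepatitis C	disease
malaria	malaria	disease
cancer	cancer	disease
cancers	cancers	disease
tumor	tumor	disease
tumors	tumors	disease
tumour	tumour	disease
tumours	tumours	disease
carcinoma	carcinoma	disease
carcinomas	carcinomas	disease
malignancy	malignancy	disease
malignancies	malignancies	disease
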