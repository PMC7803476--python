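# Bundled disease-term dictionary (common conditions, multi-word terms
# included).  Real deployments supply their own vocabulary.
cancer
lung cancer
breast cancer
colon cancer
prostate cancer
skin cancer
ovarian cancer
pancreatic cancer
stomach cancer
brain cancer
throat cancer
bone cancer
carcinoma
melanoma
leukemia
lymphoma
diabetes
diabetes type 2
type 2 diabetes
diabetes mellitus
gestational diabetes
hypertension
high blood pressure
heart disease
coronary artery disease
heart attack
myocardial infarction
heart failure
heart murmur
atrial fibrillation
stroke
asthma
copd
emphysema
bronchitis
pneumonia
tuberculosis
arthritis
rheumatoid arthritis
osteoarthritis
osteoporosis
gout
lupus
fibromyalgia
multiple sclerosis
muscular dystrophy
cerebral palsy
parkinson disease
alzheimer disease
dementia
epilepsy
seizures
migraine
migraines
depression
anxiety
bipolar disorder
schizophrenia
autism
eczema
psoriasis
obesity
high cholesterol
hyperlipidemia
thyroid disease
hypothyroidism
hyperthyroidism
goiter
kidney disease
kidney stones
renal failure
liver disease
cirrhosis
hepatitis
anemia
sickle cell anemia
hemophilia
cystic fibrosis
down syndrome
glaucoma
cataracts
macular degeneration
hearing loss
blindness
color blindness
ulcerative colitis
crohn disease
celiac disease
irritable bowel syndrome
acid reflux
ulcers
gallstones
sleep apnea
endometriosis
polycystic ovary syndrome
infertility
miscarriage
birth defects
aneurysm
blood clots
deep vein thrombosis
varicose veins
scoliosis
spina bifida
cleft palate
huntington disease
marfan syndrome
hemochromatosis
thalassemia
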