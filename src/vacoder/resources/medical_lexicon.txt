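fever
cough
abdomen
abdominal
yellow
weak
weakness
jaundice
tuberculosis
pregnancy
pregnant
cancer
tumour
tumor
breathless
breathlessness
chest
pain
vomit
vomiting
diarrhea
diarrhoea
stool
loose
dehydration
paralysis
stroke
heart
cardiac
attack
pressure
blood
bleeding
anemia
anaemia
swelling
swollen
unconscious
convulsion
convulsions
seizure
fits
headache
giddiness
dizziness
asthma
wheezing
pneumonia
sputum
phlegm
cold
chills
malaria
typhoid
dengue
cholera
measles
tetanus
sepsis
infection
infected
wound
injury
accident
fracture
burn
burns
poison
poisoning
snake
bite
hanging
suicide
delivery
labour
labor
childbirth
placenta
premature
birth
asphyxia
umbilical
cord
newborn
neonate
infant
breast
feeding
suck
cry
crying
limp
pallor
cyanosis
liver
cirrhosis
ascites
alcohol
kidney
urine
urination
diabetes
sugar
hypertension
palpitation
oedema
edema
appetite
emaciated
tired
fatigue
hospital
doctor
medicine
treatment
injection
tablet
admitted
discharged
ward
clinic
ambulance
oxygen
saline
drip
x-ray
scan
operation
surgery
bedridden
collapsed
expired
died
death
deceased
body
mouth
eyes
tongue
throat
neck
stomach
back
limbs
legs
arms
skin
rash
itching
ulcer
boil
lump
glands
night
sweats
loss
weight
thin
spitting
coughing
breathing
gasping
choking
suffocation
drowning
electrocution
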