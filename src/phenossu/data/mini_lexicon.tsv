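fever	386661006	Fever
headache	25064002	Headache
rash	271807003	Rash
bleeding	131148009	Bleeding
epistaxis	249366005	Epistaxis
abscess	128477000	Abscess
abscesses	128477000	Abscess
cough	49727002	Cough
diarrhea	62315008	Diarrhea
vomiting	422400008	Vomiting
nausea	422587007	Nausea
abdominal pain	21522001	Abdominal pain
pain	22253000	Pain
sore throat	162397003	Pain in throat
fatigue	84229001	Fatigue
chills	43724002	Chill
myalgia	68962001	Myalgia
jaundice	18165001	Jaundice
conjunctivitis	9826008	Conjunctivitis
lymphadenopathy	30746006	Lymphadenopathy
swelling	65124004	Swelling
loss of smell	44169009	Loss of sense of smell
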