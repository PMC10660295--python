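name,smiles
aspirin,CC(=O)OC1=CC=CC=C1C(=O)O
paracetamol,CC(=O)NC1=CC=C(O)C=C1
ibuprofen,CC(C)CC1=CC=C(C=C1)C(C)C(=O)O
naproxen,COC1=CC2=CC=C(C=C2C=C1)C(C)C(=O)O
caffeine,CN1C=NC2=C1C(=O)N(C)C(=O)N2C
nicotine,CN1CCCC1C1=CC=CN=C1
benzocaine,CCOC(=O)C1=CC=C(N)C=C1
lidocaine,CCN(CC)CC(=O)NC1=C(C)C=CC=C1C
procaine,CCN(CC)CCOC(=O)C1=CC=C(N)C=C1
atenolol,CC(C)NCC(O)COC1=CC=C(CC(N)=O)C=C1
propranolol,CC(C)NCC(O)COC1=CC=CC2=CC=CC=C12
metoprolol,COCCC1=CC=C(OCC(O)CNC(C)C)C=C1
salbutamol,CC(C)(C)NCC(O)C1=CC(CO)=C(O)C=C1
warfarin,CC(=O)CC(C1=CC=CC=C1)C1=C(O)C2=CC=CC=C2OC1=O
diazepam,CN1C(=O)CN=C(C2=CC=CC=C2)C2=CC(Cl)=CC=C12
phenytoin,O=C1NC(=O)C(N1)(C1=CC=CC=C1)C1=CC=CC=C1
chlorpromazine,CN(C)CCCN1C2=CC=CC=C2SC2=CC=C(Cl)C=C12
imipramine,CN(C)CCCN1C2=CC=CC=C2CCC2=CC=CC=C12
fluoxetine,CNCCC(OC1=CC=C(C=C1)C(F)(F)F)C1=CC=CC=C1
sertraline,CNC1CCC(C2=CC=C(Cl)C(Cl)=C2)C2=CC=CC=C12
metformin,CN(C)C(=N)NC(=N)N
cimetidine,CC1=C(CSCCNC(=NC)NC#N)N=CN1
sulfanilamide,NC1=CC=C(C=C1)S(N)(=O)=O
sulfamethoxazole,CC1=CC(=NO1)NS(=O)(=O)C1=CC=C(N)C=C1
trimethoprim,COC1=CC(CC2=CN=C(N)N=C2N)=CC(OC)=C1OC
chloramphenicol,OCC(NC(=O)C(Cl)Cl)C(O)C1=CC=C(C=C1)[N+]([O-])=O
isoniazid,NNC(=O)C1=CC=NC=C1
pyrazinamide,NC(=O)C1=CN=CC=N1
ethambutol,CCC(CO)NCCNC(CC)CO
metronidazole,CC1=NC=C(N1CCO)[N+]([O-])=O
ciprofloxacin,OC(=O)C1=CN(C2CC2)C2=CC(N3CCNCC3)=C(F)C=C2C1=O
norfloxacin,CCN1C=C(C(O)=O)C(=O)C2=CC(F)=C(N3CCNCC3)C=C12
nalidixic_acid,CCN1C=C(C(O)=O)C(=O)C2=CC=C(C)N=C12
fluorouracil,FC1=CNC(=O)NC1=O
methotrexate,CN(CC1=CN=C2N=C(N)N=C(N)C2=N1)C1=CC=C(C=C1)C(=O)NC(CCC(O)=O)C(O)=O
mercaptopurine,Sc1ncnc2nc[nH]c12
hydroxyurea,NC(=O)NO
busulfan,CS(=O)(=O)OCCCCOS(C)(=O)=O
chlorambucil,OC(=O)CCCC1=CC=C(C=C1)N(CCCl)CCCl
melphalan,NC(CC1=CC=C(C=C1)N(CCCl)CCCl)C(O)=O
cyclophosphamide,ClCCN(CCCl)P1(=O)NCCCO1
ifosfamide,ClCCNP1(=O)OCCCN1CCCl
dacarbazine,CN(C)N=Nc1[nH]cnc1C(N)=O
tamoxifen,CCC(=C(C1=CC=CC=C1)C1=CC=C(OCCN(C)C)C=C1)C1=CC=CC=C1
letrozole,N#CC1=CC=C(C=C1)C(N1C=NC=N1)C1=CC=C(C=C1)C#N
anastrozole,CC(C)(C#N)C1=CC(=CC(=C1)CN1C=NC=N1)C(C)(C)C#N
imatinib,Cc1ccc(NC(=O)c2ccc(CN3CCN(C)CC3)cc2)cc1Nc1nccc(-c2cccnc2)n1
gefitinib,COC1=CC2=C(C=C1OCCCN1CCOCC1)C(NC1=CC(Cl)=C(F)C=C1)=NC=N2
erlotinib,COCCOC1=CC2=C(C=C1OCCOC)C(NC1=CC=CC(=C1)C#C)=NC=N2
sorafenib,CNC(=O)C1=CC(OC2=CC=C(NC(=O)NC3=CC=C(Cl)C(=C3)C(F)(F)F)C=C2)=CC=N1
sunitinib,CCN(CC)CCNC(=O)C1=C(C)NC(=C1C)C=C1C(=O)NC2=CC=C(F)C=C12
dasatinib,CC1=NC(NC2=NC=C(S2)C(=O)NC2=C(C)C=CC=C2Cl)=CC(N2CCN(CCO)CC2)=N1
celecoxib,CC1=CC=C(C=C1)C1=CC(=NN1C1=CC=C(C=C1)S(N)(=O)=O)C(F)(F)F
indomethacin,COC1=CC2=C(C=C1)N(C(=O)C1=CC=C(Cl)C=C1)C(C)=C2CC(O)=O
diclofenac,OC(=O)CC1=CC=CC=C1NC1=C(Cl)C=CC=C1Cl
ketoprofen,CC(C(O)=O)C1=CC=CC(=C1)C(=O)C1=CC=CC=C1
mefenamic_acid,CC1=CC=CC(NC2=CC=CC=C2C(O)=O)=C1C
probenecid,CCCN(CCC)S(=O)(=O)C1=CC=C(C=C1)C(O)=O
furosemide,NS(=O)(=O)C1=CC(C(O)=O)=C(NCC2=CC=CO2)C=C1Cl
hydrochlorothiazide,NS(=O)(=O)C1=CC2=C(C=C1Cl)NCNS2(=O)=O
captopril,CC(CS)C(=O)N1CCCC1C(O)=O
enalapril,CCOC(=O)C(CCC1=CC=CC=C1)NC(C)C(=O)N1CCCC1C(O)=O
losartan,CCCCC1=NC(Cl)=C(CO)N1CC1=CC=C(C=C1)C1=CC=CC=C1C1=NN=NN1
nifedipine,COC(=O)C1=C(C)NC(C)=C(C1C1=CC=CC=C1[N+]([O-])=O)C(=O)OC
amlodipine,CCOC(=O)C1=C(COCCN)NC(C)=C(C1C1=CC=CC=C1Cl)C(=O)OC
verapamil,COC1=CC=C(CCN(C)CCCC(C#N)(C(C)C)C2=CC(OC)=C(OC)C=C2)C=C1OC
gemfibrozil,CC1=CC=C(C)C(OCCCC(C)(C)C(O)=O)=C1
clofibrate,CCOC(=O)C(C)(C)OC1=CC=C(Cl)C=C1
glibenclamide,COC1=CC=C(Cl)C=C1C(=O)NCCC1=CC=C(C=C1)S(=O)(=O)NC(=O)NC1CCCCC1
tolbutamide,CCCCNC(=O)NS(=O)(=O)C1=CC=C(C)C=C1
phenobarbital,CCC1(C2=CC=CC=C2)C(=O)NC(=O)NC1=O
primidone,CCC1(C2=CC=CC=C2)C(=O)NCNC1=O
carbamazepine,NC(=O)N1C2=CC=CC=C2C=CC2=CC=CC=C12
valproate,CCCC(CCC)C(O)=O
gabapentin,NCC1(CC(O)=O)CCCCC1
baclofen,NCC(CC(O)=O)C1=CC=C(Cl)C=C1
levodopa,NC(CC1=CC(O)=C(O)C=C1)C(O)=O
methyldopa,CC(N)(CC1=CC(O)=C(O)C=C1)C(O)=O
serotonin,NCCC1=CNC2=CC=C(O)C=C12
melatonin,COC1=CC2=C(NC=C2CCNC(C)=O)C=C1
tryptophan,NC(CC1=CNC2=CC=CC=C12)C(O)=O
histamine,NCCC1=CNC=N1
dopamine,NCCC1=CC(O)=C(O)C=C1
epinephrine,CNCC(O)C1=CC(O)=C(O)C=C1
theophylline,CN1C(=O)C2=C(N=CN2)N(C)C1=O
chloroquine,CCN(CC)CCCC(C)NC1=CC=NC2=CC(Cl)=CC=C12
primaquine,COC1=CC(NC(C)CCCN)=C2N=CC=CC2=C1
dapsone,NC1=CC=C(C=C1)S(=O)(=O)C1=CC=C(N)C=C1
azathioprine,CN1C=NC(=C1SC1=NC=NC2=C1NC=N2)[N+]([O-])=O
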