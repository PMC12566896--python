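# Steroid drug -> physiological/receptor/ATC class (18 classes).
# Curated map: canonical pharmacology assignments for the steroids under
# analysis (18 classes).
drug_name	class
ABIRATERONE	Antiandrogen
BECLOMETASONE	Glucocorticoid
BETAMETHASONE	Glucocorticoid
BUDESONIDE	Glucocorticoid
CANRENOIC ACID	Mineralocorticoid Receptor Antagonist
CHLORMADINONE	Progestogen
CHOLESTEROL	Sterol
CICLESONIDE	Glucocorticoid
CLOBETASOL	Glucocorticoid
CLOBETASONE	Glucocorticoid
COLLAGENASE	Enzyme
CORTISONE	Glucocorticoid
CYPROTERONE	Antiandrogen
DANAZOL	Androgen
DEFLAZACORT	Glucocorticoid
DEOXYCHOLIC ACID	Bile Acid
DESOGESTREL	Progestogen
DESONIDE	Glucocorticoid
DESOXIMETASONE	Glucocorticoid
DEXAMETHASONE	Glucocorticoid
DIENOGEST	Progestogen
DIFLUCORTOLONE	Glucocorticoid
DIFLUPREDNATE	Glucocorticoid
DIGITOXIN	Cardiac Glycoside
DIGOXIN	Cardiac Glycoside
DROSPIRENONE	Progestogen
DYDROGESTERONE	Progestogen
EPLERENONE	Mineralocorticoid Receptor Antagonist
ESTRADIOL	Estrogen
ESTRAMUSTINE	Estrogen
ESTRIOL	Estrogen
ESTROGENS	Estrogen
ESTROGENS CONJUGATED	Estrogen
ESTROPIPATE	Estrogen
ETHINYLESTRADIOL	Estrogen
ETONOGESTREL	Progestogen
EXEMESTANE	Steroidal Aromatase Inhibitor
FLUDROCORTISONE	Mineralocorticoid
FLUMETASONE	Glucocorticoid
FLUNISOLIDE	Glucocorticoid
FLUOCINOLONE ACETONIDE	Glucocorticoid
FLUOCINONIDE	Glucocorticoid
FLUOROMETHOLONE	Glucocorticoid
FLUTICASONE	Glucocorticoid
FULVESTRANT	Antiestrogen
FUSIDIC ACID	Steroidal Antibiotic
GESTODENE	Progestogen
HYDROCORTISONE	Glucocorticoid
HYDROXYPROGESTERONE	Progestogen
LEVONORGESTREL	Progestogen
LOTEPREDNOL	Glucocorticoid
MEDROXYPROGESTERONE	Progestogen
MEGESTROL	Progestogen
METHYLPREDNISOLONE	Glucocorticoid
METHYLTESTOSTERONE	Androgen
METILDIGOXIN	Cardiac Glycoside
MIFEPRISTONE	Antiprogestogen
MOMETASONE	Glucocorticoid
NORELGESTROMIN	Progestogen
NORETHISTERONE	Progestogen
NORGESTIMATE	Progestogen
NORGESTREL	Progestogen
OBETICHOLIC ACID	Bile Acid
PRASTERONE	Androgen
PREDNISOLONE	Glucocorticoid
PREDNISONE	Glucocorticoid
PROGESTERONE	Progestogen
ROCURONIUM	Non-steroidal Neuromuscular Blocker
SPIRONOLACTONE	Mineralocorticoid Receptor Antagonist
STEROIDS	Steroid (General)
TESTOSTERONE	Androgen
TIBOLONE	Progestogen
TRIAMCINOLONE	Glucocorticoid
ULOBETASOL	Glucocorticoid
URSODEOXYCHOLIC ACID	Bile Acid
VECURONIUM	Non-steroidal Neuromuscular Blocker
WITHANIA SOMNIFERA	Phytosteroid
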