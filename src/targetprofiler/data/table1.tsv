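target	combination	disease	status
CCK-A receptor (dexloxiglumide)	A,B,C,D	Irritable bowel syndrome	Positive results in phase III trial (2007) and a large European phase III trial (2010), in talks with FDA for approval (2010)
Coagulation factor IIa (SR-123781A)	A,B,C,D	Venous thromboembolism	Positive results in a large European phase III trial (2008)
NTRK1 (lestaurtinib)	A,B,C,D	Acute myeloid leukemia	Lestaurtinib approved by FDA as orphan drug (2006)
5HT 3 receptor (cilansetron)	A,C,D	Irritable bowel syndrome	Positive phase III trial results (2004), filed but withdrawn for FDA approval (2005), still in talks with MHRA and EU (2010)
Heparanase (PI-88)	A,C,D	Hepatocellular cancer	PI-88 fast tracked by FDA (2008)
MDR 3 (LY335979)	A,C,D	Acute myeloid leukemia
Orexin receptor (almorexant)	A,C,D	Sleep disorders	Positive phase III trial result (2010)
Somatostatin receptor 1 (pasireotide)	A,C,D	Cushing's disease, renal cell carcinoma
NK-2 receptor (saredutant)	A,C,D	Depression	Positive phase III trial result (2007), trial discontinued (2009)
BK-2 receptor (icatibant)	A,B,C	Hereditary angioedema, traumatic brain injuries	Positive phase III trial results (2006), icatibant approved in EU (2008)
Thrombin receptor (SCH-530348)	A,B,C	Cardiovascular disorders
CXCR4 (plerixafor)	A,B,D	Non-Hodgkin's lymphoma, late-stage solid tumors	Plerixafor approved by FDA (2008)
C1 esterase (Cinryze)	A,B,D	Hereditary angioedema	Cinryze approved by FDA (2008)
Sphingosine 1-phosphate receptor 1 (Gilenia)	A,B,D	Multiple sclerosis	Positive phase III trial results (2008). FDA granted priority review (2010)
NPYR5 (CGP71683A)	A,B,D	Obesity
Plasma kallikrein (ecallantide)	A,B,D	Hereditary angioedema	Positive phase III trial results (2007), ecallantide approved by FDA (2009)
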