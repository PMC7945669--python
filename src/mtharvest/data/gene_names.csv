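standard_name,variant
ND1,ND1
ND1,nad1
ND1,nadh1
ND1,MT-ND1
ND1,NADH dehydrogenase subunit 1
ND1,NADH dehydrogenase subunit I
ND1,NADH-ubiquinone oxidoreductase chain 1
ND2,ND2
ND2,nad2
ND2,nadh2
ND2,MT-ND2
ND2,NADH dehydrogenase subunit 2
ND2,NADH dehydrogenase subunit II
ND2,NADH dehydrogenase 2
ND2,NADH-ubiquinone oxidoreductase chain 2
ND3,ND3
ND3,nad3
ND3,nadh3
ND3,MT-ND3
ND3,NADH dehydrogenase subunit 3
ND3,NADH-ubiquinone oxidoreductase chain 3
ND4,ND4
ND4,nad4
ND4,nadh4
ND4,MT-ND4
ND4,NADH dehydrogenase subunit 4
ND4,NADH-ubiquinone oxidoreductase chain 4
ND4L,ND4L
ND4L,nad4l
ND4L,MT-ND4L
ND4L,NADH dehydrogenase subunit 4L
ND4L,NADH-ubiquinone oxidoreductase chain 4L
ND5,ND5
ND5,nad5
ND5,nadh5
ND5,MT-ND5
ND5,NADH dehydrogenase subunit 5
ND5,NADH-ubiquinone oxidoreductase chain 5
ND6,ND6
ND6,nad6
ND6,nadh6
ND6,MT-ND6
ND6,NADH dehydrogenase subunit 6
ND6,NADH-ubiquinone oxidoreductase chain 6
COX1,COX1
COX1,COI
COX1,CO1
COX1,COXI
COX1,MT-CO1
COX1,cytochrome c oxidase subunit 1
COX1,cytochrome c oxidase subunit I
COX1,cytochrome oxidase subunit 1
COX1,cytochrome oxidase subunit I
COX1,cytochrome oxidase c subunit 1
COX2,COX2
COX2,COII
COX2,CO2
COX2,COXII
COX2,MT-CO2
COX2,cytochrome c oxidase subunit 2
COX2,cytochrome c oxidase subunit II
COX2,cytochrome oxidase subunit 2
COX2,cytochrome oxidase subunit II
COX3,COX3
COX3,COIII
COX3,CO3
COX3,COXIII
COX3,MT-CO3
COX3,cytochrome c oxidase subunit 3
COX3,cytochrome c oxidase subunit III
COX3,cytochrome oxidase subunit 3
COX3,cytochrome oxidase subunit III
ATP6,ATP6
ATP6,ATPase6
ATP6,ATPase 6
ATP6,MT-ATP6
ATP6,ATP synthase F0 subunit 6
ATP6,ATP synthase subunit 6
ATP6,ATP synthase 6
ATP8,ATP8
ATP8,ATPase8
ATP8,ATPase 8
ATP8,MT-ATP8
ATP8,ATP synthase F0 subunit 8
ATP8,ATP synthase subunit 8
ATP8,ATP synthase 8
CYTB,CYTB
CYTB,cyt b
CYTB,cyt-b
CYTB,cob
CYTB,MT-CYB
CYTB,CYB
CYTB,cytochrome b
CYTB,cytochrome-b
CYTB,cytb gene
12S,12S
12S,12S rRNA
12S,12S ribosomal RNA
12S,rrnS
12S,s-rRNA
12S,small subunit ribosomal RNA
12S,MT-RNR1
16S,16S
16S,16S rRNA
16S,16S ribosomal RNA
16S,rrnL
16S,l-rRNA
16S,large subunit ribosomal RNA
16S,MT-RNR2
CR,CR
CR,control region
CR,D-loop
CR,Dloop
CR,mitochondrial control region
CR,control region CR
tRNA-Phe,tRNA-Phe
tRNA-Phe,trnF
tRNA-Phe,tRNA Phe
tRNA-Phe,transfer RNA phenylalanine
tRNA-Val,tRNA-Val
tRNA-Val,trnV
tRNA-Val,tRNA Val
tRNA-Val,transfer RNA valine
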