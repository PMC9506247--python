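# alias	canonical
# Case-insensitive aliases mapped to the canonical gene symbols used throughout
# the package. Edit or extend freely: this table is data, not code.
cox1	cox1
coi	cox1
co1	cox1
cox-1	cox1
cytochrome c oxidase subunit 1	cox1
cytochrome c oxidase subunit i	cox1
cox2	cox2
coii	cox2
co2	cox2
cytochrome c oxidase subunit 2	cox2
cytochrome c oxidase subunit ii	cox2
cox3	cox3
coiii	cox3
co3	cox3
cytochrome c oxidase subunit 3	cox3
cytochrome c oxidase subunit iii	cox3
atp6	atp6
atpase6	atp6
atpase 6	atp6
atp synthase f0 subunit 6	atp6
atp8	atp8
atpase8	atp8
atpase 8	atp8
atp synthase f0 subunit 8	atp8
nad1	nad1
nd1	nad1
nadh1	nad1
nadh dehydrogenase subunit 1	nad1
nad2	nad2
nd2	nad2
nadh2	nad2
nadh dehydrogenase subunit 2	nad2
nad3	nad3
nd3	nad3
nadh3	nad3
nadh dehydrogenase subunit 3	nad3
nad4	nad4
nd4	nad4
nadh4	nad4
nadh dehydrogenase subunit 4	nad4
nad4l	nad4l
nd4l	nad4l
nadh dehydrogenase subunit 4l	nad4l
nad5	nad5
nd5	nad5
nadh5	nad5
nadh dehydrogenase subunit 5	nad5
nad6	nad6
nd6	nad6
nadh6	nad6
nadh dehydrogenase subunit 6	nad6
cytb	cytb
cob	cytb
cyb	cytb
cytochrome b	cytb
rrns	rrnS
12s	rrnS
12s rrna	rrnS
12s ribosomal rna	rrnS
s-rrna	rrnS
small subunit ribosomal rna	rrnS
rrnl	rrnL
16s	rrnL
16s rrna	rrnL
16s ribosomal rna	rrnL
l-rrna	rrnL
large subunit ribosomal rna	rrnL
cr	CR
control region	CR
d-loop	CR
a+t rich region	CR
at rich region	CR
trna	trnA
trna-ala	trnA
trnc	trnC
trna-cys	trnC
trnd	trnD
trna-asp	trnD
trne	trnE
trna-glu	trnE
trnf	trnF
trna-phe	trnF
trng	trnG
trna-gly	trnG
trnh	trnH
trna-his	trnH
trni	trnI
trna-ile	trnI
trnk	trnK
trna-lys	trnK
trnl1	trnL1
trna-leu(cun)	trnL1
trnl(cun)	trnL1
trnl2	trnL2
trna-leu(uur)	trnL2
trnl(uur)	trnL2
trnm	trnM
trna-met	trnM
trnn	trnN
trna-asn	trnN
trnp	trnP
trna-pro	trnP
trnq	trnQ
trna-gln	trnQ
trnr	trnR
trna-arg	trnR
trns1	trnS1
trna-ser(agn)	trnS1
trns(agn)	trnS1
trns2	trnS2
trna-ser(ucn)	trnS2
trns(ucn)	trnS2
trnt	trnT
trna-thr	trnT
trnv	trnV
trna-val	trnV
trnw	trnW
trna-trp	trnW
trny	trnY
trna-tyr	trnY
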