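# Putative ancestral arthropod (D. yakuba-like) mitochondrial gene order,
# linearized from trnI on the J-strand. Columns: name, ftype, strand.
trnI	tRNA	+
trnQ	tRNA	-
trnM	tRNA	+
nad2	PCG	+
trnW	tRNA	+
trnC	tRNA	-
trnY	tRNA	-
cox1	PCG	+
trnL2	tRNA	+
cox2	PCG	+
trnK	tRNA	+
trnD	tRNA	+
atp8	PCG	+
atp6	PCG	+
cox3	PCG	+
trnG	tRNA	+
nad3	PCG	+
trnA	tRNA	+
trnR	tRNA	+
trnN	tRNA	+
trnS1	tRNA	+
trnE	tRNA	+
trnF	tRNA	-
nad5	PCG	-
trnH	tRNA	-
nad4	PCG	-
nad4l	PCG	-
trnT	tRNA	+
trnP	tRNA	-
nad6	PCG	+
cytb	PCG	+
trnS2	tRNA	+
nad1	PCG	-
trnL1	tRNA	-
rrnL	rRNA	-
trnV	tRNA	-
rrnS	rRNA	-
CR	control_region	+
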