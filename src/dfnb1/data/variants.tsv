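# Curated GJB2/GJB6 variant catalogue for the south-Indian assortative-mating cohort.
# Legacy protein-level names are the canonical keys; hgvs is an optional alias column
# carried for reference and unused in computation.
# effect_class vocabulary: pathogenic-recessive | pathogenic-dominant | polymorphism | novel-uncertain
gene	cdna	protein	domain	effect_class	hgvs	annotations
GJB2	c.71 G>A	W24X	TM1	pathogenic-recessive	p.Trp24Ter	most common pathogenic allele in this cohort
GJB2	c.79 G>A	V27I	TM1	polymorphism	p.Val27Ile
GJB2	c.104 T>G	I35S	TM1	pathogenic-recessive	p.Ile35Ser
GJB2	c.109 G>A	V37I	TM1	pathogenic-recessive	p.Val37Ile	represented once in this cohort
GJB2	c.126 G>T	E42D	EC1	novel-uncertain	p.Glu42Asp	novel; SIFT tolerated (0.57); PolyPhen-2 benign (HumDiv 0.038, HumVar 0.052)
GJB2	c.135 A>G	G45G	EC1	polymorphism	p.Gly45=	synonymous
GJB2	c.165 C>A	T55T	EC1	polymorphism	p.Thr55=	synonymous
GJB2	c.185 A>G	N62S	EC1	polymorphism	p.Asn62Ser	borderline class; pathogenicity configurable
GJB2	c.224 G>A	R75Q	TM2	pathogenic-dominant	p.Arg75Gln	autosomal dominant; first Indian report, non-syndromic presentation
GJB2	c.231 G>A	W77X	TM2	pathogenic-recessive	p.Trp77Ter
GJB2	c.240 G>A	Q80Q	TM2	polymorphism	p.Gln80=	synonymous
GJB2	c.257 C>T	T86M	TM2	pathogenic-recessive	p.Thr86Met	rare; first Indian report
GJB2	c.262 G>A	A88A	TM2	polymorphism	p.Ala88=	synonymous
GJB2	c.341 A>G	E114G	IC	polymorphism	p.Glu114Gly
GJB2	c.370 C>T	Q124X	IC	pathogenic-recessive	p.Gln124Ter
GJB2	c.380 G>A	R127H	IC	polymorphism	p.Arg127His	most common polymorphism in this cohort
GJB2	c.439 G>A	E147K	TM3	polymorphism	p.Glu147Lys	borderline class; pathogenicity configurable
GJB2	c.457 G>A	V153I	TM3	polymorphism	p.Val153Ile
GJB2	c.493 C>T	R165W	EC2	polymorphism	p.Arg165Trp
GJB2	c.551 G>A	R184Q	EC2	pathogenic-dominant	p.Arg184Gln	autosomal dominant; part of a unique triallelic genotype
GJB2	c.585 G>A	M195I	TM4	polymorphism	p.Met195Ile
GJB2	c.675 A>T	P225P	IC	polymorphism	p.Pro225=	synonymous
GJB2	IVS1+1 G>A	IVS1+1G>A	intronic	pathogenic-recessive	c.-23+1G>A	splice-donor site of the non-coding exon 1 (-3172 G>A)
GJB6	c.170 A>G	Q57R	EC1	novel-uncertain	p.Gln57Arg	novel missense, transition; SIFT affects function (0.00); PolyPhen-2 probably damaging
GJB6	c.301 G>C	E101Q	IC2	novel-uncertain	p.Glu101Gln	novel missense, transversion; SIFT tolerated (0.48); PolyPhen-2 benign
GJB6	c.311 G>A	R104H	IC2	novel-uncertain	p.Arg104His	novel missense, transition; SIFT affects function (0.01); PolyPhen-2 possibly damaging
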