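m_id	p_id	polypeptide	domain	f1	f2	f3	freq	plasmy	n_damaging_predictors
m.4633C>G	p.A55G	p.MT-ND2	TM	127.5	2.33	12.66	0	Ho	4
m.4648T>C	p.F60S	p.MT-ND2	TM	113.7	0.02	4.22	0	Ho	4
m.5244G>A	p.G259S	p.MT-ND2	TM	138.9	1.01	23.65	0	He	4
m.6742T>C	p.I280T	p.MT-CO1	TM	99.7	0.02	9.22	0	He	3
m.8528T>C	p.W55R	p.MT-ATP8	M	102.6	0.04	14.99	0	He	4
m.8795A>G	p.H90R	p.MT-ATP6	TM	73.8	0	0.66	0	He	4
m.9972A>C	p.I256L	p.MT-CO3	IM	112.3	0.97	25.85	1	He	1
m.10543A>G	p.H25R	p.MT-ND4L	TM	150.5	2.57	0.66	0	He	4
m.10591T>G	p.F41C	p.MT-ND4L	TM	134.9	0.02	1.08	0	He	3
m.12848C>T	p.A171V	p.MT-ND5	TM	164.3	0.16	8.93	0	He	3
m.13051G>A	p.G239S	p.MT-ND5	TM	163.9	0.02	23.65	0	Ho	4
m.13511A>T	p.K392M	p.MT-ND5	TM	98.9	0.02	3.24	0	He	4
m.13849A>C	p.N505H	p.MT-ND5	TM	61.8	0.27	5.24	0	Ho	2
m.14430A>G	p.W82R	p.MT-ND6	M	99.2	0.19	14.99	0	Ho	3
m.14498T>C	p.Y59C	p.MT-ND6	TM	143.9	0.04	2.97	0	He	3
m.15243G>A	p.G166E	p.MT-CYB	IM	115.6	0	11.92	0	He	4
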