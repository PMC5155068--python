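term	gene_id
Transmembrane transport	abgT
Transmembrane transport	acrE
Transmembrane transport	atpB
Transmembrane transport	fadR
Transmembrane transport	fecE
Transmembrane transport	fhuC
Transmembrane transport	glnP
Transmembrane transport	hslU
Transmembrane transport	kdgT
Transmembrane transport	melB
Transmembrane transport	mrcA
Transmembrane transport	mtlA
Transmembrane transport	parE
Transmembrane transport	tbpA
Transmembrane transport	yhhS
Transmembrane transport	yjhB
Nucleoside phosphate binding or nucleotide binding	ackA
Nucleoside phosphate binding or nucleotide binding	bcsA
Nucleoside phosphate binding or nucleotide binding	fecE
Nucleoside phosphate binding or nucleotide binding	fhuC
Nucleoside phosphate binding or nucleotide binding	hslU
Nucleoside phosphate binding or nucleotide binding	hyfR
Nucleoside phosphate binding or nucleotide binding	ldhA
Nucleoside phosphate binding or nucleotide binding	nadR
Nucleoside phosphate binding or nucleotide binding	nirB
Nucleoside phosphate binding or nucleotide binding	parE
Nucleoside phosphate binding or nucleotide binding	pheT
Nucleoside phosphate binding or nucleotide binding	tbpA
Nucleoside phosphate binding or nucleotide binding	yihV
Nucleoside phosphate binding or nucleotide binding	yihU
Regulated by CRP-cAMP	ackA
Regulated by CRP-cAMP	acrE
Regulated by CRP-cAMP	bhsA
Regulated by CRP-cAMP	caiB
Regulated by CRP-cAMP	fecE
Regulated by CRP-cAMP	fhuC
Regulated by CRP-cAMP	hyfR
Regulated by CRP-cAMP	malP
Regulated by CRP-cAMP	melB
Regulated by CRP-cAMP	metH
Regulated by CRP-cAMP	mtlA
Regulated by CRP-cAMP	nirB
Regulated by CRP-cAMP	nuoE
Regulated by CRP-cAMP	yhhY
Sulfur compound metabolic or biosynthetic process	ackA
Sulfur compound metabolic or biosynthetic process	metH
Sulfur compound metabolic or biosynthetic process	nadR
Sulfur compound metabolic or biosynthetic process	parE
Sulfur compound metabolic or biosynthetic process	pheT
Sulfur compound metabolic or biosynthetic process	pta
Sulfur compound metabolic or biosynthetic process	thiE
Sulfur compound metabolic or biosynthetic process	yfaU
Sulfur compound metabolic or biosynthetic process	yigB
Sulfur compound metabolic or biosynthetic process	yihV
Sulfur compound metabolic or biosynthetic process	yihU
ATP binding/adenyl ribonucleotide binding/ATPase activity	ackA
ATP binding/adenyl ribonucleotide binding/ATPase activity	fecE
ATP binding/adenyl ribonucleotide binding/ATPase activity	fhuC
ATP binding/adenyl ribonucleotide binding/ATPase activity	hslU
ATP binding/adenyl ribonucleotide binding/ATPase activity	hyfR
ATP binding/adenyl ribonucleotide binding/ATPase activity	nadR
ATP binding/adenyl ribonucleotide binding/ATPase activity	parE
ATP binding/adenyl ribonucleotide binding/ATPase activity	pheT
ATP binding/adenyl ribonucleotide binding/ATPase activity	tbpA
ATP binding/adenyl ribonucleotide binding/ATPase activity	yihV
Magnesium ion binding	abgT
Magnesium ion binding	atpB
Magnesium ion binding	glnP
Magnesium ion binding	kdgT
Magnesium ion binding	melB
Regulated by Fur	ackA
Regulated by Fur	metH
Regulated by Fur	pta
Regulated by Fur	thiE
Acetate metabolic process	fecE
Acetate metabolic process	fhuC
Acetate metabolic process	metH
Acetate metabolic process	yhhY
Regulated by NanR	nanA
Regulated by NanR	nanC
Regulated by NanR	yjhB
Regulated by CreB	ackA
Regulated by CreB	parE
Regulated by CreB	pta
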