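species	ploidy	locus	chrom	arm	position_class
P. pseudocerasus	4	5S	Chr_7	short	proximal
P. pseudocerasus	4	5S	Chr_8	short	proximal
P. pseudocerasus	4	45S	Chr_4	short	terminal
P. pseudocerasus	4	45S	Chr_5	short	terminal
P. pseudocerasus	4	45S	Chr_7	short	terminal
P. yedoensis	2	5S	Chr_7	short	proximal
P. yedoensis	2	5S	Chr_8	short	proximal
P. yedoensis	2	45S	Chr_4	short	terminal
P. yedoensis	2	45S	Chr_5	short	terminal
P. yedoensis	2	45S	Chr_7	short	terminal
P. avium	2	5S	Chr_8	short	proximal
P. avium	2	45S	Chr_4	short	terminal
P. avium	2	45S	Chr_5	short	terminal
P. avium	2	45S	Chr_7	short	terminal
P. cerasus	4	5S	Chr_8	short	proximal
P. cerasus	4	45S	Chr_4	short	terminal
P. cerasus	4	45S	Chr_5	short	terminal
P. cerasus	4	45S	Chr_7	short	terminal
P. campanulata	2	5S	Chr_6	unknown	centromeric
P. campanulata	2	5S	Chr_8	short	proximal
P. campanulata	2	45S	Chr_4	short	terminal
P. campanulata	2	45S	Chr_5	short	terminal
P. campanulata	2	45S	Chr_7	short	terminal
P. humilis	2	5S	Chr_6	unknown	centromeric
P. humilis	2	45S	Chr_4	short	terminal
P. humilis	2	45S	Chr_7	short	terminal
P. tomentosa	2	5S	Chr_6	unknown	centromeric
P. tomentosa	2	45S	Chr_4	short	terminal
P. tomentosa	2	45S	Chr_7	short	terminal
P. salicina	2	5S	Chr_6	unknown	centromeric
P. salicina	2	45S	Chr_3	unknown	centromeric
P. salicina	2	45S	Chr_4	short	terminal
P. salicina	2	45S	Chr_7	short	terminal
P. armeniaca	2	5S	Chr_6	unknown	centromeric
P. armeniaca	2	5S	Chr_8	short	proximal
P. armeniaca	2	45S	Chr_3	unknown	centromeric
P. armeniaca	2	45S	Chr_4	short	terminal
P. armeniaca	2	45S	Chr_7	short	terminal
P. dulcis	2	5S	Chr_3	unknown	centromeric
P. dulcis	2	5S	Chr_6	unknown	centromeric
P. dulcis	2	45S	Chr_4	short	terminal
P. dulcis	2	45S	Chr_5	unknown	centromeric
P. dulcis	2	45S	Chr_7	short	terminal
P. persica	2	5S	Chr_6	unknown	centromeric
P. persica	2	5S	Chr_8	short	proximal
P. persica	2	45S	Chr_4	short	terminal
P. persica	2	45S	Chr_5	unknown	centromeric
P. persica	2	45S	Chr_7	short	terminal
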