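# Synthetic stand-in control-peptide list: ten tryptic peptides of seven
# high-abundance housekeeping proteins used to normalize SRM peak areas.
# The published peptide list is not redistributable here; these sequences are
# plausible fully-tryptic proteotypic peptides chosen for the same proteins.
gene_name	sequence
GAPDH	GALQNIIPASTGAAK
GAPDH	LISWYDNEFGYSNR
RPL27A	YSVDIPLDK
RPS3	GLCAIAQAESLR
TALDO1	ALAGCDFLTISPK
TUBB	FPGQLNADLR
TUBB	YLTVAAVFR
TUBB2C	LHFFMPGFAPLTSR
UBB	TITLEVEPSDTIENVK
UBB	ESTLHLVLR
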