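# Putative Pho boxes upstream of cyanophage S-PM2d genes (differentially expressed
# set plus the Hsp20 control gene S-PM2d130).  Half-sites are upper case, spacers
# lower case.  Position is the printed signed offset of the box relative to the
# start codon; NA means no box was reported.  The S-PM2d004 promoter carries two
# separate boxes and therefore occupies two rows.  Sequences are recorded
# verbatim, including the 9-nt leading half-site of S-PM2d131.
gene_id	annotation	box	position
S-PM2d004	hypothetical protein	CTTTCCTCtcgTTTAACTG	-62
S-PM2d004	hypothetical protein	ATTATACAattCTTGGAGA	-25
S-PM2d006	hypothetical protein	NA	NA
S-PM2d074	hypothetical protein	NA	NA
S-PM2d115	hypothetical protein	NA	NA
S-PM2d118	recombination endonuclease subunit (gp46)	NA	NA
S-PM2d130	Heat shock protein (Hsp20)	ATTCAAACtcgCTTAAATA	-31
S-PM2d131	hypothetical protein	TTTGAAGATggtCTTTTGAAgatCTCACTGG	-138
S-PM2d132	hypothetical protein	CTAATCCAaacCTTGATGC	-91
S-PM2d133	DNA polymerase (gp43)	GTTAAAATatcCATATGCA	-162
S-PM2d134	UvsX RecA-like	NA	NA
S-PM2d135	DNA primase-helicase (gp41)	NA	NA
S-PM2d136	Pyrophosphatase (mazG)	CTTTTGAAgacCTTTCAACtcgCCAAAAGC	-63
S-PM2d169	hypothetical protein	NA	NA
S-PM2d172	hli2	NA	NA
S-PM2d190	hypothetical protein	NA	NA
S-PM2d216	hypothetical protein	NA	NA
S-PM2d241	hypothetical protein	CTTCCCCGccgCTGAGGTG	-105
S-PM2d250	putative ATPase	CCTATACTgatCTCAGTTC	-30
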