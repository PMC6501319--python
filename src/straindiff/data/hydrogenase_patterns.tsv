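# [NiFe]-hydrogenase motif database shipped with straindiff.
# Only motifs with a stated provenance are included; users supply further
# group patterns (e.g. the full 1b L1-L4 set) from a published
# classification scheme.  'x'/'X' is a wildcard.  The group 2b proximal
# FeS-cluster binding motif is a composite with unconstrained spacing and is
# stored as three independently scanned segments.
group	motif_name	pattern	subunit	provenance
1d	medial	xPIxSGHxCxGCx	small	described group 1d medial FeS-cluster binding motif
1d	L1	VERICGVCTGCH	large	observed sequence reported compatible with group 1d
1d	L2	SFDPCLACSTH	large	observed sequence reported compatible with group 1d
1d	L3	HDHIVHFYHLHALD	large	canonical L3 motif as reported
1d	L4	GTVAAPRGALAH	large	canonical L4 motif as reported
2b	proximal_1	xCGGCx	small	segment 1 of the described group 2b proximal composite motif
2b	proximal_2	xCxxxGG	small	segment 2 of the described group 2b proximal composite motif
2b	proximal_3	xCP	small	segment 3 of the described group 2b proximal composite motif
2b	L1	APRICGICSVSQ	large	observed sequence reported compatible with group 2b
2b	L2	SFDPCMVCTVH	large	observed sequence reported compatible with group 2b
tat	tat	RRxFxK	small	twin-arginine translocation export signal
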