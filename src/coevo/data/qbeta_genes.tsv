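# genome_length	4217
# Gene coordinates (1-based inclusive) for the Qbeta RNA genome as used with
# the synthetic reference. The A2 CDS (61-1323, 1263 nt = 29.95% of the
# genome) and the shared coat/A1 start at 1344 are pinned by the published
# genome-position/gene-position offsets; the coat stop (read through by A1),
# the A1 stop and the replicase coordinates follow the canonical Qbeta gene
# order and protein lengths and are synthetic-consistent fixture choices.
name	start	end
A2	61	1323
coat	1344	1742
A1	1344	2333
replicase	2352	4118
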