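# generation	NCBI=0	Anc=0	M54=54	M109=109	M163=163	M165_2=165	S94_3=94	S169_3=169	S168_4=168
# lineage	line1	Anc,M54,M109,M163
# lineage	line2	Anc,M54,M165_2
# lineage	line3	Anc,S94_3,S169_3
# lineage	line4	Anc,S168_4
# note	Whole-population resequencing statuses for the Qbeta copropagation (lines 1-2) and phage-only propagation (lines 3-4) experiments; NCBI is the deposited reference isolate, not an experimental population.
# note	Position 569 was heterogeneous (G and A) in the ancestral stock although it derives from cloned cDNA; the ancestral column is polymorphic there.
# note	Transcription cross-validated against the published per-line weighted counts (7.5, 7.0, 2.0, 2.5) and group means/SDs; no ambiguous cells remained.
genome_position	ancestral	evolved	NCBI	Anc	M54	M109	M163	M165_2	S94_3	S169_3	S168_4
47	G	A									±
52	A	G				±	+			±	±
66	U	A						±			
221	U	G			+	±		±			
519	A	G				±	±	±			
569	G/A	A	+	±	+	+	+	+	+	+	+
789	C	U						±			
830	U	C				±	+	±			
1257	C	U	+				±				
1288	A	G					±	±			
1344	A	G						±			
1371	G	C						+			
1795	U	C					±				
2249	C	U	+		+	+	+	+	+	+	+
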