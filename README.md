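# circmotif

Tools for identifying protein-associated circular RNAs from
co-immunoprecipitation RNA-seq and linking them to a protein's binding
motif derived from in-vitro selection (SELEX) sequencing:

* **`circ_call`** — parse chimeric alignment records (STAR-style TSV or
  SAM with supplementary alignments), apply the four back-splice selection
  criteria (same chromosome/strand with reverse-order segments, junction
  overhang ≥ 12 nt, chimeric-vs-linear score margin > 2, annotated or
  canonical GT/AG splice sites), count junction reads per library, annotate
  candidates against a GTF, select the high-confidence set (≥ 30 reads in
  at least one library) and the non-target comparison group (≥ 10 reads,
  protein-coding host, absent from the IP).
* **`selex_motif`** — demultiplex/trim/deduplicate SELEX-seq reads into
  18–20 nt tags and compute per-round k-mer (tetramer/hexamer) enrichment
  z-scores with cumulative ranking.
* **`motif_enrichment`** — summed top-10-motif occurrence density per
  100 nt for each circRNA and the target vs non-target Welch t-test with
  kernel density estimates.
* **`quant`** — qPCR primer efficiency from dilution series, percent-of-
  input (ΔΔCt) quantitation, and gradient sedimentation profile statistics.
* **`synthetic_data`** — fully seeded generators for every input: toy
  genome + GTF with canonical splice flanks, chimeric records with
  per-criterion decoys and a truth table, multi-round selection libraries
  with planted motif affinity, and circRNA groups with a planted density
  offset.

## CLI

```bash
# simulate inputs (deterministic under --seed)
circmotif simulate chimeric --seed 1 --out sim/
circmotif simulate selex    --seed 1 --out selex/
circmotif simulate groups   --seed 1 --out groups/

# junction calling and group selection
circmotif call --chimeric sim/chimeric.tsv --genome sim/genome.fa \
    --gtf sim/annotation.gtf --min-overhang 12 --score-margin 2 \
    --high-conf 30 --out call/
circmotif nontarget --expression expr_junctions.tsv --ip call/junctions.tsv \
    --gtf sim/annotation.gtf --min-count 10 --biotype protein_coding --out nt/

# SELEX enrichment
circmotif selex demux --layout selex/layout.json --out demux/ selex/R*.fastq
circmotif selex enrich --k 4 --out enrich/ demux/R*.tags.txt

# motif-density comparison
circmotif enrich --target groups/target.fa --nontarget groups/nontarget.fa \
    --motifs enrich/top10_motifs.txt --out final/

# quantitation utilities
circmotif quant qpcr --table assays.tsv
circmotif quant gradient --table profiles.tsv
```

Chimeric TSV dialect (header required, coordinates 1-based inclusive):
`record_id, library_id, chrom_a, start_a, end_a, strand_a, chrom_b,
start_b, end_b, strand_b, chimeric_score, best_linear_score`, where
segment *a* is the first part of the read.

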