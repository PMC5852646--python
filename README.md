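# mprna

Analysis toolkit for **massively parallel RNA assays (MPRNA)** — pooled
reporter experiments in which thousands of transcript segments, each tagged
with a unique barcode, are appended to a common reporter RNA and read out by
barcode sequencing. The package targets the nuclear-enrichment flavour of
the assay: which segments of a transcript are sufficient to retain an
otherwise cytosolic reporter in the nucleus. It is written for
computational biologists running (or simulating) such screens.

## What it does

The pipeline covers the assay end to end:

1. **Pool design** (`mprna.pool_design`) — transcripts are tiled into 110-nt
   windows at a 10-nt step, so each interior base is covered by 11
   overlapping oligos. Each window becomes a 153-nt oligo:
   `16-nt primer + 110-nt segment + 10-nt barcode + 17-nt primer`.
   Barcodes are sampled under a pairwise Hamming distance ≥ 3, a
   homopolymer cap, and primer 8-mer exclusion.
2. **Read mapping** (`mprna.read_mapping`) — a read is assigned to an oligo
   iff its first 10 nt exactly match a barcode and the next ≤ 90 nt match
   the expected adjacent sequence with at most 2 mismatches. Includes the
   ≥ 70 % oligo-recovery QC rule for transfection/library quality.
3. **Signal modeling** (`mprna.signal_model`) — counts are normalized to
   counts per million (CPM); the signal at transcript position *p* is the
   **median of the normalized counts of all oligos covering *p***, giving a
   per-nucleotide track at 10-nt resolution.
4. **Differential-region calling** (`mprna.region_caller`) — per position,
   d(p) = median over replicate pairs of (nuclear − total); candidate
   regions are maximal runs with d(p) above a threshold; each region gets a
   summary statistic (area × replicate consistency); a **global empirical
   null** is built by relabeling nuclear/total samples and re-running
   detection; empirical p-values are converted to q-values
   (Benjamini–Hochberg) and regions with q < 0.1 are reported. Region
   boundaries are then sharpened by deconvolving the dilution ramp that
   110-nt windows impose at region edges.
5. **Sequence statistics** (`mprna.seq_stats`) — k-mer ridge regression with
   cross-validated penalty choice, exact/asymptotic Mann–Whitney tests,
   length-matched shuffle controls constrained to exons, and a log-odds PWM
   scanner (MEME minimal format).
6. **Simulation** (`mprna.simulate`) — synthetic experiments with planted
   enrichment regions, log-normal baseline abundances, negative-binomial
   counts, oligo dropout and error-bearing reads, with full ground truth.

The model in brief: for replicate pair *i* and grid position *p*,

```
N_i(p) = median{ cpm_i(o) : o covers p, o in nuclear i }
d(p)   = median_i ( N_i(p) − T_i(p) )
stat(R) = Σ_{p∈R} d(p) × mean_p fraction of pairs with N_i(p) > T_i(p)
p_emp(R) = (1 + #{null stats ≥ stat(R)}) / (1 + #null)
```

## Worked example

```python
from mprna import (SimConfig, simulate_counts, normalize_counts,
                   model_nucleotide_counts, call_drs, regions_to_frame)

cfg = SimConfig(n_transcripts=3, transcript_length=(2000, 2000),
                effect=3.0, reads_per_sample=1_000_000, seed=42)
manifest, counts, truth = simulate_counts(cfg)
norm = normalize_counts(counts)
tracks = model_nucleotide_counts(norm, manifest)
res = call_drs(tracks, counts.samples, norm=norm, manifest=manifest)
print(regions_to_frame(res.regions))
```

Output (planted regions were tx000:1410–1710, tx001:1090–1390,
tx002:1010–1310, each at 3-fold nuclear enrichment):

```
transcript_id  start  end  n_positions         stat    p_emp        q
        tx000   1410 1700           29 46445.069696 0.005747 0.005747
        tx001   1080 1400           32 49111.936080 0.005747 0.005747
        tx002    980 1300           32 54737.876149 0.005747 0.005747
```

All three planted regions are recovered at q ≪ 0.1 with boundaries within a
few tens of nucleotides (typically ≤ 20 nt); `stat` is the area × consistency
summary on the CPM scale, and `p_emp` is the add-one empirical p-value
against the pooled permutation null (here 173 null statistics from the 63
pair-flip relabelings of 6 replicate pairs).

The same pipeline is available from the shell:

```bash
mprna simulate --out-dir sim --n-transcripts 3 --length 2000 --seed 42
mprna call --counts sim/counts.tsv --samples sim/samples.tsv \
           --manifest sim/manifest.tsv --out drs.tsv
```

plus `mprna design|map|model|kmer|stats|scan|shuffle|run` for the other
stages (see `mprna --help`).

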