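# thyrosig

Consensus fold-change analysis and aggressiveness-signature selection for
two-class thyroid-carcinoma transcriptome cohorts.

Anaplastic thyroid carcinoma (ATC) is the lethal, dedifferentiated end stage
of thyroid tumor progression; papillary thyroid carcinoma (PTC) is its
frequent, good-prognosis precursor. Comparing the two expression profiles
against a pooled normal-thyroid reference reveals largely overlapping but
unequally strong regulation programs, and a small cross-class signature that
cleanly separates the tumor types. `thyrosig` implements that analysis as a
reusable, tested pipeline for anyone working with probes × samples log2
expression matrices and per-sample class labels:

* **log2 ratios** — r[p,s] = log2 intensity of tumor s minus the probe's
  mean over the normal-pool samples;
* **unanimous consensus lists** — probes with r ≥ +log2(f) (or ≤ −log2(f))
  in *every* sample of a class, default f = 2;
* **aggressiveness signature** — probes beyond ±log2(1.5) in every sample of
  one class while *no* sample of the other class reaches the opposing
  threshold, in all four direction × class branches;
* **cohort statistics** — Venn overlap between class lists, ATC/PTC
  amplification ratio of shared regulations, qRT-PCR ΔΔCt ratios and
  direction concordance, mutation-frequency summaries;
* **ordination** — 1 − Pearson correlation distances, classical and
  nonmetric MDS (Kruskal stress-1, isotonic regression + Guttman updates),
  UPGMA clustering with Newick export;
* **ARE enrichment** — AU-rich-element proportions between probe groups
  with a two-sided Fisher exact test;
* **synthetic cohorts** — a generator that plants shared, class-restricted,
  signature and null probes with known effects and guard-banded noise, so
  every rule's recovery is testable exactly.

The core selection steps are also exposed as sklearn-style estimators
(`ConsensusSelector`, `SignatureSelector`, `NonmetricMDS`,
`LogRatioTransformer`) that compose with sklearn pipelines; the module-level
functions are thin wrappers over them.

## Worked example

```python
import thyrosig as ts

# 11 ATC + 48 PTC samples, 5000 probes, planted 9-probe signature, seed 42
ratios, sheet, truth = ts.generate_cohort(ts.SyntheticScenario())

atc = ts.consensus_lists(ratios, sheet, "ATC", threshold_fold=2.0)
ptc = ts.consensus_lists(ratios, sheet, "PTC", threshold_fold=2.0)
ov = ts.overlap_summary(ptc, atc)
sig = ts.derive_signature(ratios, sheet, threshold_fold=1.5)
emb = ts.nonmetric_mds(ts.correlation_distances(ratios), k=2, seed=0)

print(f"ATC list: {len(atc.up)} up / {len(atc.down)} down")
print(f"PTC list: {len(ptc.up)} up / {len(ptc.down)} down")
print(f"shared: {ov.shared_up} up / {ov.shared_down} down "
      f"-> {ov.pct_ptc_shared}% of PTC list")
print(f"signature: {sig.size} probes, patterns {set(sig.frame['pattern'])}")
print(f"MDS stress: {emb.stress:.3f}")
```

prints

```
ATC list: 350 up / 359 down
PTC list: 256 up / 220 down
shared: 190 up / 192 down -> 80% of PTC list
signature: 9 probes, patterns {'ATC_down/PTC_up'}
MDS stress: 0.138
```

Reading this: at the 2-fold level the ATC program is broader than the PTC
one and most PTC-consistent regulations recur in ATC (the generator plants
400 shared probes plus class-restricted ones; noise trims the unanimous
lists); the 1.5-fold cross-class rule recovers exactly the 9 planted
signature probes, every one down in all ATC and up in all PTC; and the
two classes separate in the 2-dimensional nonmetric embedding (stress 0.14
is an acceptable ordinal fit for 59 samples).

## Command line

```sh
thyrosig simulate --config scenario.yaml --outdir cohort/ --seed 42
thyrosig run --config pipeline.yaml            # full report bundle
thyrosig consensus --matrix cohort/log_ratios.tsv \
    --sheet cohort/sample_sheet.tsv --group ATC --fold 2 --out atc.tsv
thyrosig signature --matrix ... --sheet ... --out signature.tsv
thyrosig mds --matrix ... --out coords.tsv
```

`run` executes every configured stage (ratios → consensus → overlap →
signature → MDS/clustering → ARE enrichment → mutations → concordance) and
writes TSV artifacts plus a machine-readable `report.json`; a rerun with the
same config and seed is byte-identical. All inputs and outputs are plain
TSV; formats are documented in the module docstrings of `thyrosig.io`.

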