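# oriscape

Analysis of mutagenesis at human DNA replication origins: origin-centered
mutation-rate and strand-bias profiling, positional mutational-signature
extraction (SBS96/ID83) with NMF and strict refitting, origin sequence
statistics, TFBS/QTL enrichment tests, and an in silico model of origin
sequence evolution — all exercised end-to-end on a synthetic-data
generator with known ground truth.

## Who this is for

Efficient, early-firing ("constitutive") replication origins are local
mutation hotspots: DNA breaks form at their centers during licensing and
firing, and error-prone synthesis operates in their immediate flanks.
`oriscape` is for genomicists who want to quantify such origin-anchored
mutational footprints — given origin intervals with firing efficiencies
(BED), variant catalogs (VCF), a genome (FASTA), coverage tracks
(bedGraph), signature catalogs (COSMIC-layout TSV), PWMs (JASPAR) and
QTL/rank tables (TSV) — or to prototype the analysis against simulated
inputs before touching real data.

## The core quantities

* **Metagene profiles.** Every origin midpoint anchors a 20-kb domain cut
  into 100-bp windows. The mutation rate in window *w* is the count of
  variants across domains divided by the number of domains, normalized by
  the mean of the first and last 20 windows (so 1.0 = flank background).
  Composition correction divides C- and T-rooted substitution classes by
  the window's C+G or A+T base counts.
* **Replication strand bias.** For substitution b→m,
  RSB = log2(n_fwd / n_rev) per window, where n_fwd counts variants whose
  written reference is the pyrimidine. Its sign flips at origins when
  mutagenesis is replication-coupled.
* **Signatures.** Windowed 96-channel (trinucleotide) and 83-channel
  (indel) count matrices are factorized by multi-run Kullback–Leibler NMF;
  the rank is the smallest one before the consensus cophenetic
  correlation drops. Known catalogs are refit per window by non-negative
  least squares, with strict backward elimination at cosine cost
  `max_delta = 0.004`.
* **Evolution model.** Three fitted rules — where a base mutates (PDF-1,
  multipeak Gaussian over offset), what it becomes (PDF-2, signature
  exposures × channel probabilities, composition-corrected), and on which
  strand the change fixes (PDF-3) — drive rounds of mutation over a
  library of naive sequences, reproducing the GC enrichment, skew flips,
  and diversity patterns seen at real origins.

See `docs/methods.md` for the full model description and numerical
choices.

## Worked example

Generate a small synthetic study and profile it:

```python
from oriscape import landscape, signatures as sig
from oriscape.synthetic_data import SyntheticStudy, small_config

study = SyntheticStudy(small_config(), seed=1)     # 2-Mb genome, 40 origins
variants, truth = study.variants()                 # ~20,000 SNVs + indels
ds = study.domainset()                             # 200 windows x 40 origins

prof = landscape.background_normalize(
    landscape.mutation_rate_profile(variants, ds))
print(f"center fold enrichment: {prof.aggregate[95:105].mean():.2f}")
print(f"flank level:            {prof.aggregate[:20].mean():.2f}")

counts = sig.build_count_matrix(variants, study.genome, ds, kind="SBS")
res = sig.strict_fit(counts, study.reference_catalog(n_decoys=2),
                     sig.StrictFitConfig(0.004))
print(f"operating signatures:   {', '.join(res.signatures)}")
print(f"reconstruction cosine:  {res.final_cosine:.4f}")
```

prints

```
center fold enrichment: 19.75
flank level:            1.06
operating signatures:   background, center, volcano
reconstruction cosine:  0.8868
```

The planted center component enriches mutations ~20-fold over the flank
background at the origin midpoint, and strict refitting keeps exactly the
three generating signatures while eliminating both decoys; the
reconstruction cosine is limited by Poisson noise in the sparse flank
windows at this reduced scale.

A command-line layer mirrors the library:
`oriscape simulate | profile | signatures | seqfeat | evolve | enrich`
(each subcommand is a thin wrapper; run with `--help`).

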