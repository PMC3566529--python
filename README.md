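# infoconn

Informational connectivity (IC) for block-design fMRI: track, time-point by
time-point, how discriminable a condition's multi-voxel activity pattern is
within a brain region, then map the regions whose discriminability
time-courses rise and fall together with a seed region. The package also
provides the matched seed-based functional-connectivity (FC) baseline,
non-parametric cluster-corrected group inference, and a synthetic
block-design generator with known ground-truth coupling, so the whole
pipeline is testable without scanner data.

It is aimed at cognitive-neuroscience researchers doing multi-voxel pattern
analysis (MVPA) who want to ask not just *where* condition information lives
but *which regions exchange it*: univariate FC tracks synchronized
activation levels, while IC tracks synchronized fluctuations of pattern
information that can be invisible to FC.

## The metric

For each labeled time-point *n* with activity pattern **x**[*n*] over the
*m* voxels of a region or searchlight, and leave-one-run-out condition
prototypes **ȳ**<sub>c</sub> (the mean training pattern of each condition):

- *r*<sub>c</sub>[*n*] = Pearson correlation of **x**[*n*] with the correct
  condition's prototype,
- *r*<sub>i</sub>[*n*] = max over incorrect conditions' prototypes,
- **discriminability**[*n*] = artanh(*r*<sub>c</sub>[*n*]) −
  artanh(*r*<sub>i</sub>[*n*]).

Positive values mean the standard correlation classifier labels the
time-point correctly. A seed's discriminability series is compared to every
searchlight's series (spherical, 3-voxel radius, 123 voxels) by Spearman
rank correlation; each *r*<sub>s</sub> lands at the searchlight's central
voxel, giving the per-subject IC map. Maps are Fisher-transformed,
smoothed (8 mm FWHM), and entered into a one-sided group *t*-test.
Correction for multiple comparisons swaps whole stimulus blocks of the seed
series at random (100 permutations per subject), resamples them into 1000
null group maps, and takes the 50th-largest null max-cluster size as the
minimum significant cluster extent (p < 0.05, corrected).

## Worked example

```bash
python examples/02_ic_vs_fc_dissociation.py
```

simulates one subject containing four regions — a seed, a partner sharing
the seed's block-wise pattern-SNR fluctuations (but with a flat univariate
response), a partner sharing only its univariate fluctuations (with no
condition information), and an independent control — and prints:

```
region           IC r_s     FC r
seed             +1.000   +0.442
info_partner     +0.415   -0.052
uni_partner      -0.072   +0.367
independent      +0.013   +0.121
```

IC singles out the information-coupled partner (+0.415) and ignores the
univariate-coupled one (−0.072); FC shows the reverse pattern. The seed's
own center is 1.0 on IC by construction. `examples/01_discriminability_trace.py`
prints the underlying per-TR discriminability table (432 analyzed
time-points, 108 per condition) and `examples/03_group_cluster_inference.py`
runs the full permutation-corrected group analysis on a small simulated
group.

The same pipeline is scriptable from the shell:

```bash
infoconn simulate --out-dir data --n-subjects 5
infoconn group --subject-dir data/sub-00 ... --method ic \
    --conditions bottle,chair,scissors,shoe --seed-center 5 5 5 --radius 3 \
    --out-dir results/group_ic
```

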