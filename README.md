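# chronocal

Distance-calibrated divergence-time placement for newly discovered taxa.

When a new species is found and sequenced at a single locus (a 16S-style
mitochondrial fragment, say), a full dating analysis is often impossible:
one marker, few individuals, and no fossils. But if a time-calibrated
phylogeny (chronogram) already exists for its close relatives, the new
taxon can be *placed on that published timescale* by regression: under an
approximately constant substitution rate, the genetic distance between two
species grows linearly with the time since their divergence, so published
node ages regressed on measured distances give a calibration line, and the
new taxon's distance to its nearest relative can be inserted into it.

`chronocal` implements that workflow end to end, for systematists who have
an aligned FASTA, a tip-to-species table and a published ultrametric Newick
tree:

- **uncorrected p-distances** with pairwise deletion of gaps/ambiguities,
  summarised as the familiar min–max percent table between and within
  species (and the within-species check against the conspecific 0.2–0.9%
  band);
- **node ages and pairwise divergence times** extracted from an ultrametric
  chronogram, with ultrametricity checking;
- **calibration regression** y = a·x + b of divergence time (My) on percent
  distance, both unconstrained (centred R²) and constrained through the
  origin (slope Σxy/Σx², uncentred R² = 1 − SSres/Σy²);
- **placement**: nearest relative, distance summary, predicted minimum
  divergence time with a regression prediction interval (or a fixed ±half
  width), and a flag for whether the divergence pre-dates the Quaternary
  (2.58 My);
- **a Yule + Jukes–Cantor simulator** (strict clock, exact crown age,
  conspecific individuals as a shallow polytomy) that generates held-out
  focal-taxon scenarios with known truth, so the whole pipeline is
  validated without any downloads.

## Worked example

Simulate a 12-species scenario in which species `sp04` is "newly
discovered" (present in the alignment, held out of the chronogram), then
place it:

```bash
chronocal simulate --species 12 --individuals 2 --crown-age 30 \
    --mu 5e-4 --sites 1600 --seed 42 --out-dir demo
# wrote scenario to demo (focal sp04, T* = 2.834 My)

chronocal place demo/alignment.fasta --species-map demo/species_map.tsv \
    --chronogram demo/chronogram.nwk --focal sp04
```

Key fields of the JSON report (abridged):

```json
{
  "nearest_relative": "sp06",
  "nearest_range_percent": [0.5, 0.5],
  "distance_summary_percent": 0.5,
  "calibration_fits": {
    "unconstrained":  {"slope": 9.113, "intercept": 0.950, "r_squared": 0.976, "n_points": 55},
    "through_origin": {"slope": 9.473, "intercept": 0.0,   "r_squared": 0.994, "n_points": 55}
  },
  "prediction": {"point_my": 5.506, "lower_my": 2.042, "upper_my": 8.971,
                 "interval_method": "prediction_interval_0.95"},
  "predates_quaternary": false,
  "within_focal_percent": [0.3, 0.3]
}
```

Reading it: the focal taxon's nearest relative by percent distance is
`sp06` at 0.5%; regressing the published pair times of the other 11
species (55 pairs) on their distances gives y ≈ 9.1x + 0.95 My per percent
(through the origin: 9.47 — the strict-clock expectation at
μ = 5×10⁻⁴/site/My is 1/(200μ) = 10); inserting 0.5% predicts a divergence
at 5.5 My with 95% prediction interval 2.0–9.0 My, which covers the true
held-out value of 2.83 My. The two sequenced focal individuals differ by
0.3%, inside the typical conspecific band.

The same commands run on real data: `chronocal distances` for the
Table-style percent matrix, `chronocal pairtimes` for the chronogram's
species-pair ages, `chronocal calibrate` for the regression alone, and
`--fixed-halfwidth 4.0` on `place` to quote a fixed ±4 My uncertainty read
off a published figure instead of the prediction interval.

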