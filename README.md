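# aedisparity

Statistical detection of **drug–host-factor interactions** in spontaneous
adverse-event reporting databases (FAERS, VigiBase, VAERS): does a drug's
adverse-event reporting split between two host-factor groups — male/female,
under-65/at-least-65 — differently from the background for that event?
Written for pharmacovigilance analysts and biostatisticians who work with
report-level 2×2 count data.

## The model

For adverse event *i*, drug *j* and host group *s* ∈ {1, 2}, let n⁽ˢ⁾ᵢⱼ be
the report count and n⁽ˢ⁾ᵢ. the per-group margin over all drugs. Assuming
Poisson counts and conditioning on the margins, the group-1 count is
binomial under the null of no interaction:

    n⁽¹⁾ᵢⱼ | margins  ~  Binomial(nᵢⱼ, pᵢ),   pᵢ = n⁽¹⁾ᵢ. / nᵢ.

Four test statistics per 2×2 table:

- **LRT** — log likelihood ratio
  `LR = −n log(n/N) + a₁ log(a₁/M₁) + a₂ log(a₂/M₂)` (natural logs,
  0·log 0 = 0), with a Monte-Carlo null for per-drug p-values and for the
  family maximum MLR = maxⱼ LRᵢⱼ;
- **normal** — binomial z-score `z = √n (a₁/n − p) / √(p(1−p))`;
- **PRR / ROR** — proportional reporting ratio and reporting odds ratio
  applied to the host-factor split, with delta-method z-scores.

Multiplicity over the *J* drugs of a family is controlled by the
**Max-Stat** step-down procedure (reject where the statistic exceeds the
1−α quantile of the family maximum under the global null; for z-tests the
`(1−α/2)^(1/J)` normal quantile) or by **Benjamini–Hochberg** FDR. A
simulation harness measures empirical FWER, FDR and sensitivity under
partial alternatives `p′ = p + Δ·(−1)^{1(p>0.5)}` injected into a fifth of
each family's drugs.

There is no command-line tool: the importable API is the interface, and
`examples/` holds one short narrative script per capability
(ingestion → tables, testing, Monte-Carlo nulls, calibration study).

## Worked example

```sh
python examples/analgesics_sex_disparity.py
```

runs the four tests on the bundled family of twelve analgesics for the
composite liver-toxicity event (margins 47830 male / 53078 female) and
prints, among others:

```
         drug      LR  LR adj.p        z  z adj.p
acetaminophen 67.2388   0.00000 -11.5059   0.0000
      aspirin  6.1345   0.00627   3.5011   0.0055
    ibuprofen  4.4538   0.04160  -2.9749   0.0346
    meloxicam  4.3995   0.04446  -2.8949   0.0446
     etodolac  3.1308   0.14538  -2.4440   0.1610
```

`LR` is the likelihood-ratio disparity statistic and `LR adj.p` its
Max-Stat adjusted Monte-Carlo p-value over the 12-drug family (100 000
null draws of the family maximum); `z` is the signed binomial z-score
(negative = female excess relative to the event-wide male share of 47.4%)
and `z adj.p` its closed-form Max-Stat adjustment `1 − (1 − p)¹²`. Four
drugs (acetaminophen, aspirin, ibuprofen, meloxicam) show family-wise
significant sex disparity at α = 0.05.

`examples/calibration_study.py` shows the framework's operating
characteristics on synthetic data: LRT and normal hold the nominal 5%
family-wise level, while PRR and ROR inflate it several-fold — the
motivation for preferring the first two.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

rebuilds the analgesic family from its published cell counts and
recomputes, from scratch, the acetaminophen and aspirin z statistics, the
Max-Stat-adjusted normal p-values for aspirin and ibuprofen, and the
Monte-Carlo Max-Stat-adjusted LR p-value for aspirin (m = 100 000,
seedable), writing them as JSON.

## Layout

- `src/aedisparity/records.py` — report-level ingestion, composite-event
  mapping, preprocessing rules
- `src/aedisparity/tables.py` — 2×2 family construction and filters
- `src/aedisparity/stats.py` — the four test statistics
- `src/aedisparity/mcnull.py` — Monte-Carlo LR/MLR nulls
- `src/aedisparity/multiplicity.py` — Max-Stat and BH adjustments
- `src/aedisparity/simulate.py` — synthetic base generator and the
  FWER/FDR/sensitivity simulation harness
- `src/aedisparity/datasets.py` — bundled published example tables
- `docs/methods.md` — modelling assumptions, parameter choices, numerical
  conventions and known limitations
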