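# Methods

## AQVN and EIIP descriptors

For a molecule with m atomic components, nᵢ atoms of component i with
valence number Zᵢ and N = Σ nᵢ atoms in total, the average quasi-valence
number is the atom-count-weighted mean

    Z* = (1/N) Σᵢ nᵢ Zᵢ,

and the electron–ion interaction potential, derived from a general model
pseudopotential, is

    EIIP = 0.25 · (Z*/2π) · sin(1.04 π Z*),

with the sine in **radians** — the only angle convention that reproduces
the published descriptor values for the reference pesticides. Both
quantities are conventionally labelled in Rydberg units (Ry), although the
AQVN is arithmetically a dimensionless ratio; output follows the Ry
labelling convention.

The descriptor is exact rational arithmetic up to the final division:
`quasi_valence_sum` (Σ nᵢZᵢ) and `n_atoms` are integers and
`aqvn == quasi_valence_sum / n_atoms` to the last bit. Values are carried
in full double precision; 4 decimals is only the display convention.
Reference values printed elsewhere to 4 decimals appear truncated rather
than rounded in one case (boscalid, exact value 2.91428…), so comparisons
in the test suite use a 5×10⁻⁴ tolerance instead of string equality.

### Valence-number convention

The default table is

| element | H | C | N | O | S | P | F | Cl | Br | I |
|---------|---|---|---|---|---|---|---|----|----|---|
| Zᵢ      | 1 | 4 | 5 | 6 | 6 | 5 | 1 | 1  | 1  | 1 |

The halogen value of 1 (rather than the 7 of a "count the valence
electrons" convention) is forced by the published descriptor values of the
chlorinated reference compounds: boscalid C18H12Cl2N2O gives
102/35 = 2.9143 and chlorantraniliprole C18H14BrCl2N5O2 gives
126/42 = 3.0000 exactly only with halogens at 1, while the oxygen-only
abamectins confirm C:4, H:1, O:6. The table ships labelled
(`eiip-default-v1`) and any user table can be substituted via a
two-column CSV; which convention the original EIIP literature intended is
documented here rather than adjudicated.

### Formula grammar

Formulas are sequences of `ElementSymbol [count]` tokens with one level of
parenthesised groups (`CH3(CH2)2OH`), whitespace-insensitive, counts ≥ 1,
any token order (output is canonical Hill notation). Isotope brackets,
charges and hydrate dots are rejected with positioned errors: the
descriptor is defined on plain element multisets, and silently accepting
notation it cannot honour would corrupt results. Parsing accepts all IUPAC
element symbols; valence or mass lookups for elements outside the shipped
tables fail loudly with the element named.

Average molecular masses use the IUPAC 2021 conventional standard atomic
weights (Da) and serve as a cross-check of the parser against published
molecular-weight tables at one decimal place.

## Ellman assay model

### Analysis chain

1. **Initial rate** — ordinary least-squares slope of absorbance vs time
   (AU/min) over the full trace or a user window. OLS on the near-linear
   early phase is the standard microplate estimator; a decreasing trace
   returns a negative rate with a warning rather than an error.
2. **Blank correction** — the mean linear trend (offset and slope) of the
   blank wells is subtracted from every trace. This removes chromogen
   background and instrument drift and is idempotent: after one pass the
   blanks average to a zero trend. Background hydrolysis of the chromogen
   is treated as part of this constant/linear background rather than
   modelled kinetically.
3. **Percent inhibition** — 100·(1 − v/v₀) against the mean blank-corrected
   uninhibited-control rate; technical replicates are averaged per
   concentration. A non-positive control rate is an assay failure and an
   error, not a number.
4. **IC50 fit** — four-parameter log-logistic dose-response with bottom and
   top fixed at 0% and 100% by default (both releasable), unweighted least
   squares over (log IC50, Hill slope) via `scipy.optimize.curve_fit`. The
   standard error of the IC50 comes from the covariance of the log-IC50
   parameter by the delta method (SE = IC50 · SE_log). The covariance-based
   SE of a single fit and the scatter of independent repeats are different
   estimators; this package reports the former and leaves replicate-level
   SE to the caller, who has the replicate results.
5. **Censoring** — if mean inhibition at the top tested concentration is
   below 50%, the result is censored as `gt:<c_max>` ("IC50 greater than
   the highest dose tested"), mirroring how no-activity outcomes are
   reported in assay tables. Data *above* 50% everywhere are the opposite
   failure (no lower limb of the transition) and raise a
   "no transition observed" error instead of extrapolating.

### Simulator

The simulator emulates the microplate protocol the analysis targets:
50 µL inhibitor dilution + 100 µL substrate/chromogen mix + 50 µL enzyme
in a 200 µL final volume, read at 405 nm, 25 °C, every 15 s for 5 min,
three technical replicates. Defaults (all overridable):

| parameter | default | unit | origin |
|---|---|---|---|
| final acetylthiocholine [S] | 0.5 | mM | 1 mM in the 100 µL mix, halved in-well |
| final DTNB | 0.25 | mM | 0.5 mM in the mix, halved in-well |
| final enzyme activity | 0.001875 | U/mL | 0.0075 U/mL stock × 50/200 |
| Km | 0.1 | mM | order-of-magnitude typical for cholinesterase/acetylthiocholine |
| ε(TNB, 405 nm) | 13 600 | M⁻¹cm⁻¹ | standard literature value |
| path length | 0.58 | cm | 200 µL in a 96-well geometry |
| baseline A₀ | 0.05 | AU | chromogen background folded into a constant offset |
| read noise σ | 0.005 | AU | plausible plate-reader noise |
| inhibitor series | 8-point two-fold from 1000 µM | µM | covers the 0–500 µM range typically assayed and brackets mid-hundreds IC50s |

Well velocities follow Michaelis–Menten kinetics with reversible
inhibition, v = Vmax·[S]/(Km·α + [S]·α′) with α = 1 + I/Ki and α′ = 1
(competitive) or α′ = α (noncompetitive); 1 U/mL of enzyme yields
1 mM/min of product, and absorbance follows Beer–Lambert,
A(t) = A₀ + ε·l·v·t + N(0, σ²) per read. Traces are generated in the
linear regime; a specification implying more than 10% substrate depletion
over the run attaches a warning instead of silently violating the model.
When the ground truth is given as an IC50, the equivalent Ki follows from
the Cheng–Prusoff relation IC50 = Ki·(1 + [S]/Km) in competitive mode and
IC50 = Ki in noncompetitive mode.

One integer seed drives all noise; each well draws from its own
deterministic substream (`numpy` `SeedSequence.spawn`), so a fixed seed
reproduces a plate byte-for-byte regardless of platform.

### What the simulator does and does not emulate

It reproduces the geometry, kinetic law, chromophore optics, replicate
structure and additive read noise of the protocol. It does **not** model
substrate depletion curvature, enzyme inactivation over the run, solvent
(MeOH) effects on activity, buffer-composition effects, chromogen
autohydrolysis kinetics (only its constant offset), pipetting error
(noise is per-read, not per-well), or plate position effects. Pipeline
tests passing on simulated plates therefore validate the *analysis
arithmetic* — rate extraction, blank correction, dose-response fitting,
censoring — not the biochemical fidelity of any laboratory dataset.
Experimental IC50s from real assays are measurements, not quantities this
package can recompute.

### Numerical choices

- Rate estimation uses `numpy.polyfit` degree 1; no robust loss. Outlier
  reads are visible in the fit RMSE instead.
- The IC50 fit is initialised from the first log-linear interpolated 50%
  crossing, Hill slope 1; non-convergence of `curve_fit` is reported via
  `converged=False`, never as silent NaN.
- Inhibition values are never clipped for fitting; clipping is a display
  concern only.
- Concentrations at 0 µM (controls) are excluded from the dose-response
  fit; the fit requires ≥ 4 distinct positive concentrations.
- Plate analysis sorts concentrations ascending, making results
  independent of row order in the input file.

## Problem sizes in the test suite

Property tests run 50–100 randomized compositions; pipeline-recovery
checks use 20 seeded plates of 30 wells × 21 reads each, and
Cheng–Prusoff checks use three substrate concentrations at zero noise —
sizes at which the statistical criteria (median recovery error, 10%
consistency bands) are stable from run to run.

## Known limitations

- The valence convention is fixed by reproducing published descriptor
  values, not derived from first principles; descriptors for S/P-rich or
  organometallic compounds depend on table entries that have no such
  anchor (metals are absent from the default table and fail loudly).
- AQVN/EIIP are screening descriptors; nothing here claims they predict
  cholinesterase inhibition, mutagenicity or any other endpoint.
- Ki is carried as an annotation (e.g. simulator ground truth) but never
  estimated from data — no Lineweaver–Burk/Dixon analyses are included.
- The censoring rule keys on the 50% crossing only; partial inhibitors
  with a true plateau below 100% need the free-asymptote fit and
  judgement.
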