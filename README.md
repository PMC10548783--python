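# mtconform

Tools for judging how well a metallothionein (MT) "conforms" to a bound
metal ion from heteronuclear NMR observables, and for following the
sequence changes that shaped metal preference along a reconstructed snail
MT lineage.

Metallothioneins are small Cys-rich proteins that chelate Zn²⁺, Cd²⁺ or Cu⁺
in metal–thiolate clusters. When an MT binds a metal it is adapted to, the
complex settles into a single well-defined structure; a poorly matched
metal leaves the protein hopping between conformations. That conformational
exchange has clean NMR signatures in a [¹⁵N,¹H]-HSQC spectrum:

* **millisecond (intermediate) exchange** broadens peaks beyond detection —
  fewer peaks than the one-per-amide expectation;
* **much slower exchange** yields duplicate, typically weak, peaks — more
  peaks than expected;
* a **stable fold** shows the expected ~60 peaks with homogeneous
  intensities and long transverse (T₂) relaxation times.

`mtconform` quantifies these signatures for anyone analysing CPMG T₂ series
and HSQC peak lists of small proteins:

* **T₂ fitting** — per-peak nonlinear least squares of
  `I(t) = I₀·exp(−t/T₂)` with a resampling error model: the fitted initial
  intensity is resampled 500× from its standard error, T₂ is refit with I₀
  held fixed for each draw, each refit T₂ is perturbed once by its own
  standard error, and the standard deviation of the resulting values is the
  reported error. Fits with errors above 25 ms are excluded.
* **Peak-intensity inhomogeneity** — for the `k = 60` most intense peaks
  (zero-padded when fewer are visible),
  `S = mean(|I/Ī − 1|)`; `S = 0` for a perfectly homogeneous spectrum and
  `S = 2(k−n)/k` when only `n` equal peaks remain.
* **Conformity verdict** — a complex is *conform* when mean T₂ ≥ 140 ms and
  S ≤ 0.55 (both configurable), with an exchange-regime call from the peak
  count.
* **Lineage descriptors** — per-branch substitution counts over an
  alignment and tree, substitution persistence in descendants, identity to
  the ancestral sequence, side-chain bulkiness (Zamyatnin volumes) and the
  K/N (Lys/Asn) ratio from the first conserved Cys onward.
* **Ensemble comparison** — averaged pairwise RMSD between two NMR
  structure bundles for Cα or Cys-Sγ selections, domain-wise.
* **Synthetic data** — generators for relaxation tables, spectra, evolved
  alignments and toy bundles with recorded ground truth, so the entire
  pipeline is testable offline; this includes a deterministic 61-sequence
  stand-in for the snail MT lineage.

## Worked example

```python
import numpy as np
from mtconform import (RelaxationSeries, fit_exponential, monte_carlo_error,
                       select_top_k, inhomogeneity, summarize_spectrum,
                       assess_conformity)
from mtconform.synthetic import RegimeSpec, simulate_spectrum

# 1) fit one CPMG series (delays in ms)
t = np.array([20, 50, 75, 100, 125, 150, 200, 250, 300], float)
rng = np.random.default_rng(0)
series = RelaxationSeries("G12", t, 50*np.exp(-t/80) + rng.normal(0, 1, t.size))
fit = fit_exponential(series)
err = monte_carlo_error(series, fit, n_resamples=500, seed=1)
print(f"T2 = {fit.t2_ms:.1f} ms +/- {err:.1f} ms")

# 2) inhomogeneity of an exchange-broadened spectrum (30 of 60 peaks left)
print("S =", inhomogeneity(select_top_k(np.full(30, 5.0), k=60)))

# 3) full verdict on a simulated stable spectrum
table, _ = simulate_spectrum(RegimeSpec.for_regime("stable", seed=4))
report = assess_conformity(summarize_spectrum(table, k=60), mean_t2_ms=178.3,
                           expected_peaks=66)
print(report.conform, report.regime)
```

prints

```
T2 = 81.9 ms +/- 2.4 ms
S = 1.0
True stable
```

The fitted T₂ recovers the generating 80 ms within its error; a spectrum
with half its peaks broadened away scores `S = 1.0` (well above the 0.55
delimiter); the stable spectrum with long T₂ is called conform.

## Analysis scripts

`analysis/` holds numbered drivers that run the whole study on synthetic
inputs and write tables under `results/`:

1. `01_simulate_inputs.py` — panel of protein–metal conditions (stable,
   broadened, duplicate-peak and mixed regimes) plus the lineage
   alignment/tree;
2. `02_relaxation_fits.py` — per-peak T₂ fits, Monte-Carlo errors, 25 ms
   filter, mean-T₂ table;
3. `03_conformity.py` — S, peak counts and conformity verdicts per
   condition;
4. `04_lineage_descriptors.py` — substitution bookkeeping, bulkiness and
   K/N along the lineage;
5. `05_bundle_rmsd.py` — domain-wise averaged pairwise RMSD of two toy
   bundles.

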