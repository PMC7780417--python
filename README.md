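# roldsis

Exact, parameter-free regression for high-dimension/low-sample-size (HDLSS)
data, built around the idea of constraining the regression axis to the
subspace spanned by the observations — plus the single-channel ERP analysis
pipeline that motivates it: DWT feature extraction, psychometric stimulus
calibration, axis geometry with bootstrap reliability, and a cross-validated
benchmark against shrinkage regressors. A synthetic experiment generator with
planted ground truth makes the whole pipeline testable offline.

## The core idea

Given M observations x_i in R^N (N >= M) with scalar attributes y_i, the
centered observations span an (M-1)-dimensional subspace. Restricting the
affine model y = a + b'x to that subspace turns the underdetermined problem
into an even-determined M x M system with a unique exact solution: the fit
interpolates every observation with zero residual, and the recovered axis b
equals the minimum-norm exact solution. No regularization parameter, no
cross-validation.

## Package layout

| Module                | Contents |
|-----------------------|----------|
| `roldsis.core`        | `ObservationSet`, `RoldsisFit`, `spanned_basis`, `fit`, `predict`, `project_observation` |
| `roldsis.wavelet`     | periodized orthogonal DWT with the length-8 least-asymmetric filter |
| `roldsis.features`    | baseline correction, trial rejection, averaging, `decompose`/`reconstruct`, scalograms, SNR estimation |
| `roldsis.psychometrics` | sigmoid fit `p(t) = 100/(1+e^{beta (t-t0)})`, stimulus selection, max slope |
| `roldsis.axes`        | angle between axes, hyperspherical coordinates, bootstrap axes, PCA-LDA reliability, population scalograms |
| `roldsis.benchmark`   | stratified folds, ridge/lasso/sparse-PLS, CV-error tuning, overdetermined OLS sweep |
| `roldsis.simulate`    | planted axes/templates/trials/responses with known ground truth |
| `roldsis.cli`, `roldsis.io` | command-line entry points and delimited-text/JSON readers and writers |

## CLI

All randomness flows through explicit `--seed` flags; outputs are CSV/JSON
with schema-version stamps.

```sh
# synthetic experiment with a 60-degree planted angle, noiseless
roldsis simulate --seed 1 --angle 60 --noise-sd 0 --out exp/

# exact fit of both attributes; reports the angle between the two axes
roldsis fit --data exp/ --out fit.json

# project observations onto a fitted axis
roldsis project --data exp/ --fit fit.json --attribute phi --out proj.csv

# bootstrap reliability (resample trials, refit, PCA-LDA separability)
roldsis bootstrap --data exp/ --replicates 100 --seed 0 --out boot.json

# cross-validated comparison against ridge/lasso/sparse PLS
roldsis benchmark --data exp/ --methods roldsis,ridge --folds-range 3 6 \
    --seed 0 --out bench.json

# time-frequency export of a fitted axis
roldsis scalogram --data exp/ --fit fit.json --attribute phi --out scal.csv

# psychometric sigmoid fit from a vot_ms,response CSV
roldsis psychometric --responses responses.csv --out psy.json
```

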