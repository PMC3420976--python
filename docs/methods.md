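# Methods

## The model family

A rigid sphere of radius `R` approaching an observer head-on at constant
speed `v` collides at time `t_c`; its distance is `d(t) = v (t_c − t)`.
The observer sees only the angular size `θ = 2 arctan(R/d)` and its rate
of expansion `θ̇ = 2Rv/(d² + R²)`; the angular acceleration
`θ̈ = 4Rv²d/(d² + R²)²` is carried along for the alternative-model
analyses.  From these, the package evaluates:

- **τ = θ/θ̇** — for small angles an estimate of the remaining time to
  contact; exact enough that `τ ≈ t_c − t` whenever `R/d ≪ 1`.  On an
  exact trace τ is not monotone: it has a minimum shortly before contact
  where `2d·arctan(R/d) = R`, i.e. at `d = 0.4289779·R` (computed by
  bisection; a brute-force grid argmin agrees).
- **η = C·θ̇·exp(−αθ)** — the transient firing-rate model of
  collision-sensitive neurons (locust LGMD/DCMD).  Its maximum always
  occurs at the fixed angular size `2 arctan(1/α)`, i.e. at distance
  `αR`, so the peak leads contact by `α·(R/v) + δ` with δ a latency.
- **m-Tau = θ/(μ + θ̇)** — τ with a leakage constant μ (rad/s) in the
  denominator.  It equals τ times the gain `θ̇/(μ + θ̇)`, is bounded by τ,
  and has a pre-contact maximum at `d̂ = sqrt(R² + 2Rv/μ)` under the
  small-angle approximation, hence a peak lead time
  `t_c − t̂ = sqrt(x² + 2x/μ)` with `x = R/v`.  Larger objects peak
  earlier (size effect), faster approaches at fixed `t_c` peak later
  (velocity effect), and the local slope of the lead-vs-x curve falls
  monotonically toward 1 as μ grows.
- **corrected m-Tau (Ξ)** — m-Tau plus a weighted, low-pass-filtered
  version of the positive correction `ρ = μθ/(θ̇(μ+θ̇)) = τ − m-Tau`:

      Ξ = θ/(μ+θ̇) + w·μ·θ̂/(θ̂̇·(μ+θ̂̇) + ε) + κ

  where `θ̂, θ̂̇` come from first-order low-pass filters
  `x̂[k] = ξ·x̂[k−1] + (1−ξ)·x[k]` initialised with the first trace
  samples.  With `w=1, ξ=0, ε=0, κ=0`, Ξ equals τ exactly
  (algebraic identity); with `w=0, κ=0` it is m-Tau.  Its noise behaviour
  is bracketed by two limit functions: raw τ as μ→0 (poor suppression)
  and τ on the filtered variables (`lp_tau`) as μ→∞ (strong
  suppression).

## Parameters and defaults

| parameter | meaning | unit | default | note |
|---|---|---|---|---|
| μ | leakage | rad/s | 1.0 | sweeps Ξ between its limit functions |
| w | correction weight | – | 1.0 | 0 → η-like transient, 1 → ttc estimator |
| ξ_θ, ξ_θ̇ | filter memories | – | 0 | 0 = no filtering; 0.9–0.99 used for noise suppression |
| κ | offset | s | 0 | negligible in practice; kept for the optimizer |
| ε | denominator guard | – | 1e−12 | any small positive value; 0 allowed for identity checks |
| dt | time step | s | 1e−3 | resolves all filter dynamics used here |
| n_avg | estimate window | samples | 50 | 50 ms at dt = 1 ms |

Filter updates use the current input sample (`x̂[k]` depends on `x[k]`),
which avoids a one-sample dead time in Ξ.  Numeric peaks are grid
argmaxes refined by 3-point parabolic interpolation; ties between equal
maxima report the earliest sample without refinement, boundary maxima
and constant series are flagged rather than refined.

## Noise model

Angular size and velocity are perturbed independently with centred
Gaussian deviates, either multiplicatively (`x·(1 + p·N)`, constant SNR
along the approach) or additively (`x + p·N`, SNR improves as the object
looms).  Relative mode is the default for generic noise studies; the
psychophysical simulation uses absolute mode (with clipping at zero)
because only then does estimation reliability improve toward contact and
differ between object sizes the way the discrimination data require.
Streams are split per channel from one seed; batch simulations draw one
(trials × samples) matrix per condition and channel, so trial *i* is
reproducible independently of the trial count.

## Simulated discrimination experiment

Each trial shows the approach until the presentation time `t_p`, well
before contact.  The observer runs Ξ on the noisified trace, averages
the last `n_avg` samples up to and including `t_p` (inclusive window),
predicts contact at `t_p` plus that average, and answers "later" when
the prediction exceeds the reference time `t_ref` (exact ties count as
"before").  Per condition, `n_trials` independent trials give the
proportion of later responses; a least-squares cumulative Gaussian
`Φ((ttc − m)/s)` fitted over the ttc levels summarises each curve by its
point of subjective simultaneity `m` and spread `s` (`s` bounded below
by dt; flat curves are flagged degenerate rather than fitted).

The shipped default design — seven ttc levels 2.0–3.5 s, reference
2.75 s, five presentation times 0.5–2.5 s, disc diameters 4 and 8 cm,
starting distances drawn from 10–25 m with `v = d0/ttc` — mirrors the
stated shape of the human experiment with invented magnitudes, all
overridable in config.  Pairings with `t_p ≥ ttc` are skipped at
enumeration.  The generator emulates decision statistics only: no lapse
or guess rates, no response times, no learning across sessions, and no
binocular cues, so passing tests constrain the model observer, not
human idiosyncrasies.

## Grid-search optimization

The observer has eight free parameters (μ, w, ξ_θ, ξ_θ̇, κ, p_θ, p_θ̇,
n_avg).  A constant-step grid over any subset is enumerated in a fixed
lexicographic parameter order; each cell's simulated proportion curves
are scored against the observed ones with an unweighted RMSE and an
outlier-insensitive robust error (median absolute residual by default;
mean-absolute and trimmed-mean variants selectable).  Scores sort
ascending, rank one is best, ties break by enumeration order, and the
combined-size table averages the two sizes' scores before re-ranking.
All cells share one noise seed (common random numbers), so ranking
differences reflect parameters rather than draws.  ε is fixed, not
searched.

## Linearity masking

Peak lead times `sqrt(x² + 2x/μ)` over a log-spaced x grid are averaged
over `n_trials` noisy draws with per-x standard deviation `c·x`
(default c = 0.15) and fitted by weighted least squares with weights
inversely proportional to the variance of the trial mean (unit weights
when noise-free, which reduces exactly to OLS).  Linearity is "not
rejected" when a KS test on standardised residuals gives p > 0.05 while
the regression F test is significant; a perfect fit reports KS p = 1 by
convention since there is no residual distribution to test.  On
noise-free curves the KS diagnostic needs a dense grid (≈200 points) to
expose the curvature — r² alone stays above 0.98 and never flags it.
The scatter of fitted (intercept, slope) pairs is summarised by the
eigendecomposition of their 2×2 sample covariance, axes scaled to one
standard deviation.

## Firing-rate fits

Rate traces indexed by time relative to collision are fitted by
`A·f(t + δ) + baseline` for f ∈ {η, m-Tau, inverse-τ, θ̈}; positive δ
advances the stimulus function, so the intercept of the peak-vs-x line
equals δ.  Amplitude and baseline are profiled out in closed form
(linear least squares); the shape parameter (α or μ) and δ are found by
Nelder–Mead from five log-spaced starts spanning four decades, ties
going to the smaller shape parameter.  Inverse-τ and θ̈ have no shape
parameter that could move their maximum, so only A, δ and baseline are
free for them; their peak-vs-x slopes are fixed at 0.4289779 and
1/√3 ≈ 0.57735 respectively, well below η-like slopes of ~2, which is
why they underestimate η-generated peak data.  Goodness of fit reports
RMSE, r² and the F statistic against the constant-mean model with
df = (k−1, n−k) for k fitted parameters.  Real recordings are not
bundled; synthetic η-shaped traces with seeded relative noise stand in
for them, and the CSV reader accepts any user-supplied trace.

## Problem sizes

The shipped checks use: 100 random stimuli for the identity suite, 50
for the peak oracles (2000-sample traces), 100 trials × 100 repeats for
the masking experiment, 100 noisy traces for the suppression ordering,
200 trials per condition over 13 ttc levels × 3 presentation times for
the psychometric surface, a 27-cell grid × 20 repeats × 200 trials per
condition (dt = 5 ms) for parameter recovery, and 50 seeds for the
noisy self-fit.  These sizes give stable Monte-Carlo statistics while
keeping the full run in the minutes range.

## Known limitations

- Closed-form peak locations hold under the small-angle approximation;
  for wide objects near contact the numeric peak is authoritative.
- The biophysical firing-rate equation from which m-Tau derives (and
  its inhibitory extension) is out of scope; only the equilibrium form
  is implemented.
- Noise is temporally white per channel; correlated or Poisson spiking
  noise is not modelled.
- The zero-noise recovery check requires a design whose ttc levels
  separate the grid cells' deterministic decision thresholds; with
  coarse levels many cells tie at score zero and rank one is decided by
  enumeration order.
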