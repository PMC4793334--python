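# Methods

## The estimation problem

A banded bird that is shot and reported yields one (banding region,
recovery region) pair. Aggregated over decades these pairs carry strong
information about migratory connectivity, but they are thinned by two
nuisance processes: the bird must be harvested (probability *h*) and its
band must be reported (probability λ, which depends on the band type —
mail-in bands from the solicitation era report far less often than
web-address bands, and reward bands report at nearly one). The model
treats the recovery probability of a banded bird as

    pi_ij = Psi_ij * lambda * h,      D_ij ~ Binomial(N_i, pi_ij)

with Psi the 7×7 movement matrix (rows on the probability simplex), N_i
the number of birds banded in region i, and D_ij the recovery counts.

### Identifiability

λ and *h* are confounded: the likelihood depends only on their product.
The model therefore makes no attempt to separate them — *h* is held to a
single continental prior and λ is anchored per band type to its externally
known reporting probability. Psi stays identifiable because each row sums
to one: the recovery *proportions* across destination regions determine
Psi, while the row's total recovery rate determines λh. The test suite
verifies this directly: rescaling the λ prior mean by c and the *h* prior
mean by 1/c leaves the Psi posterior unchanged to within measured
Monte-Carlo error.

### Record selection

Only birds banded in the preseason window (1 Jul–30 Sep) and recovered in
hunting-season months (Oct–Feb) are used. A *direct* recovery — one in the
hunting season immediately following banding — that occurred in the
banding region is removed, because the bird had no opportunity to move;
direct recoveries in a *different* region are kept. Hunting seasons
straddle the new year: January/February recoveries are attributed to the
season that began the previous calendar year, so a January direct recovery
is correctly excluded. Rules apply in a fixed order
(preseason → has-recovery → season-months → direct-same-region) so audit
counts are reproducible. All windows are configurable (`FilterConfig`);
the Oct–Feb month set reflects the fall-to-winter migration period and can
be adjusted where flyway hunting frames differ.

### The binomial denominator

N is taken per banding region (each row i of D shares N_i), the only
reading under which D_ij ≤ N_i is guaranteed and regional banding effort
is respected; a `n_mode="global"` option fits the shared-total variant for
sensitivity. N_i is tallied from banding-only rows in the input (every
preseason-banded record, recovered or not); when the input holds
recoveries only, a separate banded-totals table must be supplied.

The independent-binomials likelihood is used as the primary form. A
multinomial alternative with an explicit never-recovered cell
(`likelihood="multinomial"`) is provided; with recovery probabilities of a
few percent the two are numerically very close, and the binomial form is
the package default.

## Priors

| parameter | prior | default | notes |
|---|---|---|---|
| Psi rows | symmetric Dirichlet(α) | α = 1 | flat on the simplex ("uninformative") |
| λ (per band type) | Beta(mean·s, (1−mean)·s) | moment-matched | `beta_from_mean(mean, strength)`: mean = the band type's known reporting probability; strength s expresses how certain that value is (50 in the examples) |
| *h* | Beta(2, 19) | as printed | see below |

The Beta(2, 19) harvest prior has analytic mean 2/21 ≈ 0.095, although it
is conventionally associated with a continental harvest mean of 0.055
(its mode, 1/19 ≈ 0.053, is close to that value — the parameters were
plausibly chosen by mode). Both readings are supported:
`h_prior_mode="as_printed"` (default) uses Beta(2, 19);
`"mean_matched"` uses a Beta with mean 0.055 at the same strength 21
(α ≈ 1.155, β ≈ 19.845). Because λh is data-identified whenever recoveries
are present, the choice has little effect on Psi.

## Sampler

Metropolis-within-Gibbs over blocks:

* **Psi rows** — Dirichlet proposal centred at the current row
  (concentration = per-row scale, plus a 0.1 floor so near-zero cells stay
  proposable), with the exact Hastings correction. The scale adapts during
  burn-in toward 25% acceptance.
* **λ, h** — Gaussian random walks on the logit scale (Jacobian-corrected),
  adapting toward 44% acceptance.
* **λh ridge** — a joint move λ → λe^ε, h → he^(−ε). The likelihood is
  invariant along this direction, so without it the confounded pair mixes
  very slowly even though Psi and the product λh mix well.
* Blocks with no likelihood contribution (rows with N_i = 0; λ and h when
  the matrix is empty) are drawn exactly from their priors, making
  data-free runs exact prior samplers.

Defaults: 2 chains, 3000 iterations, burn-in = half, thin 1. Chains start
from dispersed prior draws; a master seed spawns one independent
generator per chain, so runs are bit-reproducible. Convergence is
summarised by the Gelman–Rubin potential scale reduction factor per scalar
(49 Psi cells + λ + h), clamped at 1 from below; any R-hat above 1.1
flags the fit as non-converged (it is reported, never silently accepted).
Correctness of the sampler is anchored to an exact 1-D grid-quadrature
oracle on two-region problems (posterior mean and SD within 0.005), not to
any particular MCMC software.

## Combining band types

Each band type k is fitted separately; results are combined with weights
w_k proportional to the recoveries contributed (`weight_by="bandings"` is
available for sensitivity). The combined posterior is the mixture
Σ w_k · posterior_k, realised by *exact weighted pooling*: every draw of
type k carries weight w_k divided by that type's draw count, and the
combined mean/SD/credible intervals are weighted moments and quantiles of
the pooled sample. This is the infinite-resample limit of mixture
resampling — deterministic, free of extra Monte-Carlo noise, and unbiased
by unequal chain lengths between types. The combined mean is exactly
Σ w_k mean_k, so row-stochasticity is preserved. A `mean_only` mode
combines the per-type summary tables instead of full posteriors.

Derived per-region summaries (with CIs propagated from the pooled draws):
stay probability Psi_ii; movement to wintering regions Σ_{j wintering}
Psi_ij; and northward movement Σ_{rank(j) > rank(i)} Psi_ij under an
integer north ordering in which the wintering regions rank south of all
breeding regions (S Atlantic < Interior ≈ N Atlantic < SE ≈ SW Canada <
NE ≈ NW Canada). Ties within a latitude band mean east–west movement is
never counted as northward; the ordering is overridable.

## Synthetic data

`simulate_dataset` inverts the model: per cohort (band type, region, year)
each bird draws a destination from the true Psi row and is
recovered-and-reported with a single Bernoulli(λ_k·h) — deliberately
collapsing harvest and reporting, mirroring the model's confounding.
Banding dates are uniform over the preseason; recovery dates fall in
hunting months of the banding-year season or later, except that birds
which stayed in their banding region always wait at least one season (a
same-season stay would be discarded by the direct-recovery rule and the
ledger could no longer be exact). A ledger records the exact per-cell
recovery counts, banded totals and (optionally) planted filter-rule
violations, so filtering and matrix construction are verified count for
count. With `filter_noise`, bait records violating each selection rule are
planted in known numbers.

`make_paper_scale_scenario` is the built-in demonstration world: three
band types with **placeholder** reporting probabilities (mail-in 0.32 to
1997, web 0.70 from 1998, reward 0.98 every fifth year — the real
per-type values are unpublished), harvest rate 0.055, cohorts spread over
seven regions and the 1951–2011 banding years sized so the expected number
of reported recoveries is ≈ 15,000 (≈ 600,000 bandings), matching the
scale of the historical filtered dataset. Its movement matrix encodes
flyway fidelity, heavy Atlantic-coast wintering, near-zero stay
probabilities for the northern breeding regions and modest northward
movement out of the US regions.

What the generator does *not* emulate: survival/mortality beyond the
single recovery Bernoulli, time-varying movement or harvest, age/sex
structure, geographic coordinates, and location-reporting error. A green
end-to-end test therefore establishes that the pipeline recovers the
parameters of *this* generative structure — not that the model is robust
to violations of it.

## Numerical choices

* Probabilities are floored at 1e-300 (and capped below 1) inside
  log-likelihoods; boundary proposals evaluate to −inf and are rejected
  rather than raising.
* MH ratios drop state-independent binomial normalising constants; the
  public `log_posterior` keeps all constants and is tested cell-for-cell
  against independent scipy density evaluations.
* Weighted quantiles use the inverse-CDF convention (first value whose
  cumulative weight reaches the target), which makes degenerate weights
  (w = (1, 0)) reproduce a single type's summary exactly.
* Adaptation runs only during burn-in, so retained draws come from a
  fixed transition kernel.

## Known limitations

* Movement is assumed time-invariant: all years are pooled into one
  matrix, so long-term trends in connectivity are invisible by design.
* λ and h are not estimable from these data; results inherit whatever
  error is in the supplied reporting probabilities (scaling errors common
  to all types cancel in Psi, type-specific errors do not).
* Band types with very few recoveries get near-prior posteriors yet still
  receive (small) weight in the combination.
* The seven regions are labels; nothing constrains movement by distance
  or adjacency, and boundary-straddling local movements count as
  region-to-region movement.
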