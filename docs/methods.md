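# Methods

## Model and assumptions

The package implements monotone threshold contagion on weighted,
undirected networks. Nodes are susceptible or infected; infection is
permanent, so every trajectory ends in a frozen absorbing state. A
susceptible node with strength q_k > 0 adopts when its partial strength
satisfies q_m >= phi*q_k; equality counts as adoption, and floating-point
ties are resolved with a relative tolerance of 1e-12 on q_k. Nodes with
k = 0 receive no influence and can only be infected spontaneously.

All synthetic substrates are configuration-model networks: a prescribed
degree sequence, stub-matched and repaired to a simple graph, with edge
weights drawn i.i.d. from the weight distribution, independent of
topology. The analytical machinery (AMEs) assumes exactly this ensemble —
locally tree-like graphs with uncorrelated weights — which is why the
Monte Carlo and AME engines can be compared quantitatively. Real networks
with degree-weight correlations, communities or clustering are outside
what the solvers describe exactly (the simulator itself runs on any
`WeightedNetwork`, including imported signed networks).

## Monte Carlo scheme

One time step (sweep) is N single-node updates; each update draws a node
uniformly at random *with replacement* and advances time by 1/N. The
alternative (random permutations per sweep) has the same mean-field limit;
with-replacement is the standard asynchronous convention and is what the
time axis of the AMEs corresponds to. Within an update, the spontaneous
channel (probability p) is tried first; if it fails, the threshold rule is
checked. Partial strengths are maintained incrementally — each infection
pushes its edge weights onto the neighbours — so an update is O(1) and an
infection O(degree). The inner loop is numba-compiled and seeded
explicitly: identical (network, config, seed) give identical trajectories.

Trajectories are sampled every 0.1 sweeps (configurable) and record the
infected density rho plus the per-type edge fractions E^II (both ends
infected, the cascade bulk) and E^SI (susceptible-infected, the cascade
surface), which are NaN while their edge category is empty. Runs stop at
`t_max`, at a target density `rho_stop`, or at full infection.

## Weight schemes

* **bimodal** (n = 2): strong weight w1 = mu + sigma*sqrt((1-delta)/delta)
  with probability delta, weak weight w2 = mu - sigma*sqrt(delta/(1-delta)).
  Mean mu and population standard deviation sigma hold exactly;
  sigma_max = mu*sqrt((1-delta)/delta) is the diluted limit where w2 = 0.
  Networks with w2 = 0 are representable in memory (the TSV reader still
  rejects non-positive weights, so diluted networks are generate-and-
  simulate only).
* **lognormal**: parameterised by the mean and standard deviation of the
  weight itself; the underlying normal parameters are solved analytically.
* **empirical**: resampling of a supplied weight list, optionally
  contracted towards its mean by w' = mu + alpha*(w - mu), which preserves
  the mean and scales the standard deviation by alpha in [0, 1] while
  keeping the distribution's shape.

For the AMEs, continuous or empirical distributions are discretised into n
equal-probability quantile bins represented by their conditional means
(mean-preserving); the bimodal scheme is exact with n = 2.

## AME systems and closures

Classes are indexed by per-type degree and infected-neighbour vectors
(**k**, **m**); for uncorrelated weight assignment the degree vector of a
degree-k node is multinomial(k; type probabilities). The class equations
are closed through the mean rates at which a j-type susceptible neighbour
of a susceptible (beta_j^s) or infected (beta_j^i) node becomes infected.
Both rates average the stepwise rate F over *susceptible* classes, since
the flipping node on any edge is its susceptible end: an S-S edge of type
j is one of the k_j - m_j free edges of a susceptible node, so beta_j^s
weights classes by k_j - m_j, while an I-S edge is one of the m_j infected
edges of a susceptible node, so beta_j^i weights classes by m_j. This
m_j-weighted closure is what makes the infected-side observables (E^II)
match simulation; categories with no mass get rate 0, which only matters
at the initial instant. The reported nu_j from the full system is the
pooled ratio of infected to total j-type edges of susceptible nodes.

The reduced system evolves (nu, rho) with binomial mixtures B_{k,m}(nu_j)
restricted to threshold-satisfying classes, a size-bias factor k_j/z_j
(z_j the mean number of j-type edges), and the cumulative spontaneous
term f_t = 1 - (1-p)e^{-pt}. The binomial argument is nu_j, the standard
closure; the reduction is exact for stepwise rates, and the test suite
holds the full and reduced solutions to within 1e-4 of each other (in
practice they agree to ~1e-8). Classes with k = 0 are excluded from the
threshold sums (their rate is p, carried entirely by f_t); with q_k = 0
the threshold inequality would otherwise be trivially true and the initial
growth rate would exceed p.

Integration uses scipy's LSODA with rtol 1e-8 / atol 1e-10, sampled on the
same 0.1-sweep grid as the simulator. Initial condition: all mass
susceptible at **m** = 0 and (nu, rho) = (0, 0), i.e. an infinitesimal
random seed; the initial growth rate of rho is exactly p. Power-law degree
supports are truncated at cumulative probability 1 - 1e-6 and
renormalised; the full system refuses to build beyond 5x10^5 classes
(its cost grows roughly as k^3 per degree at n = 2), so broad-degree AMEs
need a modest explicit degree cutoff.

## Cascade observables and sweeps

t_a is the first crossing of rho = 0.75 (configurable), linearly
interpolated between samples, `inf` when never crossed within the window
(a partial cascade). Sweep cells with the Monte Carlo engine average
per-rep t_a over 25 realisations (the benchmark default) and flag the
cell `inf` when at most half the realisations cross; the sigma = 0
reference for t_r is computed with the same engine and, for MC, on the
same topology realisations (shared seeds), which cancels most realisation
noise in t_r. Boundary curves phi(sigma) = (**m**·**w**)/(**k**·**w**) are
rational in sigma for the bimodal case; curves identical as rational
functions (after cross-normalising coefficients) are merged and carry all
contributing class labels.

## Default study conditions

Benchmarks follow the k = 7 regular network with bimodal weights, mu = 1,
delta = 0.5, p = 2e-4, N = 10^4, 25 Monte Carlo realisations, target
density 0.75. The skewed-weight (partial cascade) scenario uses mu = 3,
delta = 0.2 with sigma = 5 (inside the diluted limit sigma_max = 6) at
phi = 0.25 and a 150-sweep window: there the cascade plateaus near
rho = 0.65 — the sparse strong links that drive it are exhausted — and
only creeps past 0.75 via spontaneous infections near t = 370, while the
unweighted system crosses around t = 115-135 per realisation, so the
window separates the regimes robustly on both sides. Power-law degree
sequences default to exponent tau = 2.5, k_min = 2, and an upper cutoff of
k_max = 1000 (configurable; some quoted ensemble averages imply an
unstated cutoff, and this default reproduces a truncated-zeta mean degree
of about 4.7).

Unit-test problem sizes (N = 500-3000, 6-10 realisations) are chosen so
the suite doubles as a fast regression check; the quantitative MC-AME
agreement at full benchmark scale (N = 10^4, 25 reps, 5% on t_a) lives in
the acceptance tests.

## What the synthetic generator does and does not emulate

The generator reproduces the ensemble the theory assumes: exact degree
sequences, maximal randomness otherwise, i.i.d. weights. It does not
produce degree-weight (Granovetter-type) correlations, communities,
clustering, or directed/temporal structure, so passing tests demonstrate
correctness of the model and solvers on that ensemble — not that real
networks behave identically (empirical substrates can be imported as
weighted or signed TSV edge lists and simulated directly; signed networks
are mapped to bimodal weights with delta measured as the positive-tie
fraction).

## Known limitations

* The full AME is practical only for modest degree supports and few weight
  types (class count grows combinatorially); the reduced system is the
  workhorse for sweeps.
* MC cascade-onset times carry a finite-size delay relative to the
  N -> infinity AME (noticeably below N ~ 5x10^3), so quantitative engine
  comparisons should use N >= 10^4.
* Only monotone threshold dynamics is implemented; the rate function is
  stepwise by construction (recovery or non-monotone processes are out of
  scope).
* Stub-matching repair falls back to a Havel-Hakimi construction plus
  randomising edge swaps for rigid dense sequences (e.g. the complete
  graph), where the repair swaps cannot complete; such sequences admit
  few realisations anyway.
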