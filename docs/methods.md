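# Methods

## Model and transformations

The core model is linear opinion pooling: opinions $x_i(t) \in [0,1]$,
update $X(t+1) = W X(t)$ with $W$ row-stochastic and constrained to the
links of a symmetric adjacency matrix that includes self-links.  Ordinal
scores enter through the interval-property assumption: an $n$-point scale
partitions $[0,1]$ into $n$ equal bins, a score maps to its bin midpoint
$(x-0.5)/n$, and a continuous opinion maps back to bin
$\lceil y\,n\rceil$ (with $y=0$ assigned to bin 1).  Composite scales that
start above 1 (e.g. an 8–32 sum score) are first shifted to $1..n$ by
subtracting one less than their minimum; `shift_to_unit_start` does this.

Numerical choice: before the ceiling, $y\,n$ is snapped to the nearest
integer when within $10^{-12}$ of it.  Bin midpoints never sit on
boundaries, but simulated trajectories can produce values intended to be
exact boundaries that float arithmetic nudges upward; without the snap they
would jump a bin.

## Extensions used for misspecification

*Bounded confidence*: at each step, weights between agents whose current
opinions differ by strictly more than $\Delta$ are zeroed symmetrically and
each affected row is rescaled by $1/(1-\text{removed mass})$.  Self-weights
never qualify for removal.  If a row loses all its mass (only possible when
the self-weight is zero), it falls back to unit self-weight — the agent
simply keeps its opinion.  Rows that lose nothing are returned unchanged
(not renormalised), which makes $\Delta = 1$ an exact, bitwise no-op.

*Decay*: $X(t+1) = ((1-\lambda^t) I + \lambda^t W)X(t)$.  The exponent
starts at $t = 0$ for the first update, so the first step is always a
full-weight step ($\lambda^0 = 1$) and $\lambda = 1$ disables the
extension exactly.

When both extensions are active the composition order is: mask first (the
mask, evaluated at the pre-update opinions, defines the effective weight
matrix at time $t$), then the decay convex combination with the identity.
The order is not dictated by the dynamics' definitions; treating the decay
adjustment as acting on whatever weight matrix is in force at time $t$ is
this package's documented choice.

## Fitting

Only the plain DeGroot model is fitted — when the generating process has
$\Delta < 1$ or $\lambda < 1$ the fit is deliberately misspecified, and the
extension parameters are never estimated.  The modeled trajectory starts
from the forward-transformed observed scores at $t=0$ and steps through
*every* integer time index up to the last observed step, so panels with
gaps (observations at $t = 0$ and $t = 3$, say) still accumulate indirect
influence through the unobserved steps.  The objective sums, over agents
and observed steps after $t = 0$,
$B(\hat x, x)\,\lvert\hat x - x\rvert$ — continuous deviation gated and
weighted by the bin distance $B$.  The $t=0$ term is identically zero by
construction and is not evaluated; unobserved steps are never scored.
Panels with missing values are rejected with an explicit error; imputation
is the caller's responsibility.

The genetic algorithm encodes a candidate weight matrix as a chromosome
whose genes are rows.  Per generation:

* **survival**: the best `elite_count` chromosomes pass unchanged;
* **selection**: each offspring draws two parents by size-`selection_size`
  tournament;
* **crossover** (rate 0.4): whole genes are exchanged with the second
  parent, each with probability 1/2;
* **blending** (rate 0.4): each gene becomes a convex combination
  $u\,g_1 + (1-u)\,g_2$ with one uniform $u$ per gene;
* **mutation** (rate 0.2 per gene): Gaussian noise (sd 0.1) is added to the
  gene's permitted entries, the gene is clipped at zero and renormalised.

All operators map feasible chromosomes (row sums 1, entries in $[0,1]$,
structural zeros of the supplied adjacency) to feasible chromosomes, so the
population is feasible in every generation without repair.  A row driven
entirely to zero by mutation falls back to unit self-weight; the diagonal
is always a permitted entry, so this is well defined.  Defaults —
population 100, up to 3000 generations, elitism 1, early stop at objective
0 (`tolerance`; negative disables early stopping) — are this package's own
choices: the operator vocabulary is standard for evolving
simplex-constrained rows, and the budget comfortably recovers noiseless
small-network panels while keeping a full study cell under ~2 s.  All are
exposed in `GAConfig`.

Because perfectly fitting weight matrices are generally not unique
(coarse scales and short panels leave wide level sets), `DeGrootModel.fit`
supports multiple independently seeded runs; entrywise averaging of the
run estimates preserves row-stochasticity and shared structural zeros and
is exposed via `average=True`.

## Synthetic-data generator and study design

The generator emulates the data a small peer-network intervention yields:

* **Network**: Erdős–Rényi with edge probability $d/(N-1)$ ("target degree"
  $d$), rejected until connected; sizes $N \in \{10, 20, 50\}$,
  $d \in \{5, 9\}$.  Real friendship clusters are clustered and degree-
  heterogeneous; an ER cluster is a deliberate simplification standing in
  for one recruited cluster of a larger community network.
* **Weights**: self-weights from Beta with mean 0.5 and concentration
  $\alpha+\beta=4$ (Beta(2,2)); the remainder of each row is split evenly
  across neighbours by default (a symmetric-Dirichlet split is available —
  which of the two an analyst prefers is genuinely open, and uniform is the
  more conservative default).
* **Initial opinions**: i.i.d. Uniform(0,1); trajectories simulated for 20
  further steps under the cell's $(\Delta, \lambda)$, then back-transformed
  to the $n$-point scale ($n \in \{5,7,10,20,30\}$).
* **Sampling**: the seed is a maximum-degree agent (ties broken by the
  cell's own generator); each neighbour of the seed is recruited by one
  Bernoulli($p$) trial, then each untried neighbour of each wave-1 recruit;
  two waves only, one trial per agent ever, decliners excluded for good.
  $p \in \{0.5, 1\}$, mirroring roughly half of nominees agreeing to
  participate in practice.  Samples with fewer than four agents discard the
  whole draw (network and all) and regenerate.
* **Adjacency varieties** handed to the fitter: `correct` (true links among
  sampled agents), `build` (recruitment-chain links only: same-wave links
  dropped, each wave-2 agent keeps one uniformly chosen sampled wave-1
  neighbour), `remove` (all links among non-seed agents added; the seed is
  assumed unlinked to anyone it did not name), `complete` (all ones).

The fitter receives the sampled agents' ordinal scores for $t = 0..T-1$
($T \in \{2,3,6\}$) and one variety.  Scoring: recovery RMSE over the
variety's permitted entries — except build runs, which are scored against
the correct matrix so wrongly assumed structural zeros are penalised — with
the true weight matrix reduced to sampled agents *without* renormalising
(mass on missing agents is simply unaccounted for); modeling and prediction
RMSEs against the latent continuous trajectory simulated on the full
network; ordinal-fit RMSE from bin deviations scaled by $n$.

What passing the study's checks does **not** show about real data: the
generator has no clustering, no degree–influence correlation, no opinion
noise beyond discretisation, interval-valid ordinal scales, and
error-free link reports; real panels also carry missing values the fitter
refuses rather than imputes.

Seeding: each (cell, replicate) derives its seed by hashing the cell's
field tuple together with the master seed, so results are independent of
grid order and worker count; the GA seed is drawn from that stream.  The
full factorial design (14,400 cells × 10 replicates) is available behind
`--full-grid`; the default reduced grid and the reported contrasts use one
base cell ($N=10$, $d=5$, $T=6$, $p=0.5$) with 30 replicates per
condition, enough to make the qualitative orderings stable from run to
run while keeping a laptop run in minutes.

## Known limitations

* GA hyperparameters are defaults, not tuned per dataset; very coarse
  scales with two time steps routinely admit many perfect fits, and a
  perfect ordinal fit should not be read as parameter recovery.
* Bounded-confidence/decay parameters are generator-side only; fitting them
  is out of scope.
* Directed influence, more than two recruitment waves, and
  eligibility-screening simulation are not modelled.
* The leader/non-leader summary is sensitive to correctly estimated
  structural zeros; an optional exclusion threshold is provided but no
  single convention is imposed.
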