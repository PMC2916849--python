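# Methods

## Model overview

`grnsim` simulates the evolution of a single gene-regulatory module in a
population of Z haploid, asexually reproducing individuals under
Wright-Fisher (fitness-proportional) reproduction. An individual's genome
is an ordered list of genes: M phenotypic genes whose steady-state
expression levels *are* the phenotype, and N regulatory genes whose
products act as transcription factors. Each gene carries a cis-regulatory
region of L sites — each site an integer motif identifier (*cis-number*)
in [1, n] plus a fixed real interaction coefficient in [−5, 5] — and a
coding region carrying a single motif identifier (*trans-number*). A
regulator binds every site whose cis-number equals its trans-number; the
strength of a realized interaction is the algebraic sum of the matching
sites' coefficients, so multiple sites for the same factor produce dosage
effects.

The motif space has n = round(4^m / 2) distinct words for motifs of m
base pairs (the 1/2 accounts for motif orientation); the standard values
are m = 7.14, n = 9950. The probability that a given factor has at least
one site in an L-site region,

    C_mut = 1 − (1 − 1/n)^L,

is simultaneously the per-redraw probability that a regulatory mutation
*gains* an interaction, so the gain/loss bias of interactions is
α ≈ (1 − C_mut)/C_mut. L is the natural knob for C_mut
(L = 10, 30, 100, 303, 1000 ↔ C_mut = 10⁻³ … 10⁻¹ at n = 9950).

## Expression dynamics

Development iterates the synchronous map G_i(t+1) = Φ(x_i(t)) from the
all-zero state, with regulatory input x_i = b_i + Σ_j B_ji·E_ji(t) (basal
level plus coefficient-weighted expression of all factors bound at each
site). Gene R₁ is a receptor: its protein binds its targets only while
the external signal is present, giving each genome two phenotypes φ⁺ and
φ⁻ (signal on/off). The activation function is the saturating Michaelis
form Φ(x) = E_max·x/(K + x) for x > 0, else 0, with K = 15 (the input
threshold/half-saturation) and E_max = 10, which keeps every level in
[0, 10). The exact algebraic forms of the update, activation and
steady-state criteria were genuinely open design choices here; each is
isolated behind a single function or config key (`activation_form`,
`relaxation`) so alternatives (a Hill sigmoid; inertial updates
G(t+1) = (1−λ)G + λΦ) can be substituted without touching callers.

Steady state is declared at the first t ≥ window (window = 50) at which
the population variance of every phenotypic gene's levels over the last
window+1 steps is ≤ V (V = 10⁻⁴); the phenotype is the windowed mean at
that time. Raw (unnormalized) variance is used. Development that has not
settled by t_max = 500 is lethal. The inner time loop is numba-compiled;
a pure-Python fallback keeps the package functional without numba.

## Fitness and selection

With D⁺, D⁻ the Euclidean distances of φ⁺, φ⁻ from their optima Θ⁺, Θ⁻
(Θ⁻ ≡ 0: off-signal expression is wasteful), suitability is the Gaussian

    S = exp(−(D⁺² + D⁻²)/(2σ²)),  σ = 1,

i.e. a product of per-condition Gaussians (equivalently one Gaussian on
the concatenated 2M-vector) — the symmetric way to combine the two
conditions, reducing to a single Gaussian when one is optimal. The
expression cost is Q = c·(T⁺ + T⁻), where T± are the summed expression
levels of all genes over the developmental steps of each run (up to
steady state; a config flag accrues to t_max instead) and c = 10⁻⁵ per
unit. Fitness is the multiplicative load F = S·max(0, 1 − Q) (a
subtractive alternative max(0, S − Q) is available by config); lethal
individuals have F = 0. Offspring are sampled with probability
W_i = F_i/ΣF, repeatedly until Z viable offspring exist.

## Fluctuating optimum

Θ⁺ starts at the founder's φ⁺ and shifts once every round(1/f)
generations by Euclidean distance d: in a uniformly random direction
(random-walk; direction via normalized Gaussians, rejection-sampled so
every coordinate stays in [θ_min, E_max]) or toggling between two fixed
points at distance d (cyclic). The exclusion floor θ_min (default 0.5)
implements the assumption that the optimum avoids the vicinity of zero
expression, keeping loss-of-expression mutations deleterious; its exact
value is a documented knob, not a published constant.

## Mutation

Six operators, all pure (copy-on-write): basal-level ±1 (floored at 0;
BTL), single-site cis-number redraw on [1, n] (CIS; coefficients are
never mutated), trans-number redraw (TRA), whole-gene duplication (DUP)
and deletion (DEL) of non-receptor regulatory genes, and horizontal
transfer (HOR) inserting a fully random regulatory gene. Per-gene rates
default to 10⁻⁶ (HOR 0). μ_CIS is per *gene* (a uniformly chosen site
when the gene is hit), matching the per-gene rate convention of the
other types. Horizontally acquired genes get b = 0 (they must be
activated by the network to express; config `hor_basal`). BTL applies to
phenotypic genes as well.

Scheduling modes: `per_gene` (independent Bernoulli per eligible gene ×
type — implemented as exact binomial counts with uniform targets, which
is distributionally equivalent and vectorizes across offspring);
`per_individual` (one Bernoulli per type at 10× the per-gene rate, at
most the first success applied — the 10× compensates the founder's 10
regulatory genes); `constant_PS` (per-individual, with DUP/DEL/TRA draws
re-targeted until the mutation is phenotypically Significant, so that
P_S = 1 for exactly those types whose P_S otherwise tracks network
structure; CIS/BTL are left untouched).

## Assays

*Gene classes.* After the signal-on development, a regulatory gene is
expressed iff its windowed-mean steady level exceeds ε_expr = 10⁻²
(mirroring the loss-of-phenotype threshold); silent otherwise. Among
expressed genes, *core* genes have a directed path to a phenotypic gene
whose intermediate nodes are expressed regulators (edge sign is ignored:
repression is regulation; structural edges count regardless of
expression of the target); the rest are *pseudo-expression*.

*Mutational-effect spectrum.* Single mutations of each type are applied
to core-gene targets in sampled individuals (sampling with replacement).
Loss-of-phenotype: the mutant fails to settle, or some phenotypic gene's
signal-on level drops below 10⁻². Non-effect: the concatenated
two-condition phenotype displacement is ≤ ε_same = 10⁻⁶ (exact floating
equality is unreliable; the threshold is a config key). Significant:
the rest, contributing ‖Δφ‖₂ to D_S (mean; median by flag).
P_L + P_N + P_S = 1 holds exactly by construction. D_S concatenates both
signal conditions (a flag restricts to signal-on).

*Fitness effects.* In tracking mode the run records, for every mutation
at its generation of incidence, the c = 0 fitness of the mutant versus
its unmutated parent against the optimum current at that generation.
Effects within ±10⁻² of zero are neutral (results are qualitatively
stable for bands 10⁻⁴–10⁻¹); the headline contrasts are Nb(DUP) − Nb(DEL)
and Pb(DUP) − Pb(DEL).

*Evolvability and benchmark.* Evolvability is summarized as
n_core × P_S (mutational target size × probability a core-gene mutation
is Significant). The adaptation benchmark freezes a new static optimum
at unit distance from the population mean φ⁺ (direction random within
bounds) and records D_i, the optimum-to-mean-phenotype distance, over
1000 benchmark generations.

*Degree distributions.* Interaction graphs of replicate populations are
stacked as disjoint components of one assembled GRN; binary in/out-degree
histograms over k ≥ 1 are fitted by nonlinear least squares (counts, not
proportions, matching frequency axes) to power-law a·k^(−γ), exponential
a·e^(−bk) and Poisson a·λ^k e^(−λ)/k! laws, compared by Gaussian-error
AIC = N·ln(RSS/N) + 2p (p = 2 each; constants dropped consistently).
Initial guesses a = max count, γ = 2, b = 1/mean k, λ = mean k, plus 3
jittered restarts; a never-converging model gets AIC = +∞. Fits need at
least 4 distinct degrees, else the fit is declared indeterminate.

## Founders and initial populations

A founder is drawn with connectivity C_init = 0.5 by sampling cis- and
trans-numbers uniformly on [1, n_init], n_init = round(1/(1 −
(1−C_init)^(1/L))) (= 145 at L = 100), coefficients uniform on [−5, 5],
and b = 1 for the first half of the gene list (config: random half).
Cis-numbers not matching any regulator's trans-number are re-randomized
into [1, n] excluding all current trans-numbers. Candidates are rejected
until both developments settle and all phenotypic levels are < 0.01 with
the signal off and > 2.0 with it on. The population starts clonal; the
optimum starts at the founder's φ⁺.

## Desk-scale study conditions

The cluster-scale standard conditions (Z = 10⁵, 50,000 generations,
60–100 replicates) are preserved as configuration defaults but are not
what the test suite runs. Desk-scale runs use Z = 300 and 3,000–10,000
generations with all five per-gene rates scaled to μ = 0.1/Z, which
preserves the population mutational supply Zμ = 0.1 per gene and type
per generation — the quantity that sets the rate of adaptive
substitution. Because the drift scale also shrinks with Z, the
expression-cost load is raised in the directional experiments
(c = 5×10⁻⁵–10⁻⁴ instead of 10⁻⁵) so that the per-expressed-gene cost
term stays selectively visible (Zs ≳ 10) rather than collapsing into
neutrality; without this the weak-fluctuation arm inflates by pure
drift. Under these conditions the qualitative contrasts (core-gene
growth under strong versus weak optimum fluctuation; the
beneficial-duplication excess; the non-accumulation of horizontally
transferred genes) are expected in the same direction as at cluster
scale, with much wider replicate-to-replicate spread. Directional claims
are therefore tested as one-sided tests at α = 0.05 over 8–20
replicates, not as point reproductions of figure values. The
neutral-drift check runs at Z = 100 with two marked, fitness-identical
genotypes.

What the desk-scale generator does *not* emulate: the near-deterministic
substitution regime of Z = 10⁵ populations (drift is much stronger at
Z = 300), the 50,000-generation approach to mutation–selection–drift
equilibrium of GRN size, and smooth degree distributions (which need
~100 replicate modules; the fitting code is exercised on synthetic
noiseless histograms and on small assembled GRNs instead). Passing tests
demonstrate directional and structural fidelity, not figure-level
quantitative reproduction.

One contrast is intrinsically hard at this scale and its test reflects
that: the difference in *core-gene count* between strong (d = 0.1,
f = 0.1) and weak (d = f = 10⁻³) random-walk fluctuation. At large Z the
expression cost makes every superfluous expressed gene strongly
deleterious (Zs ~ 10³), pinning the weak-fluctuation arm near its pruned
minimum, while adaptive duplications accumulate under strong
fluctuation. At Z of a few hundred the same cost term has Zs ~ 10, so
core counts in *both* arms perform episodic drift-driven expansions and
collapses; the between-replicate spread (SD ≈ 2.5 genes) is comparable
to the expected arm difference (≈ 1–1.5 genes), so a rank test at
α = 0.05 over ~10 replicates detects the direction only with ~50%
power. The suite's directional test asserts both the expected direction
of the means and the rank test; resolving the latter reliably requires
cluster-scale replication (tens of replicates at Z ≳ 10⁴).

## Numerical and design notes

- Determinism: one master seed spawns named PCG64 streams (founder,
  mutation, selection, environment, assay); runs are bit-reproducible
  from (config, seed). Development results are cached per genotype and
  shared by unmutated offspring — exact, since development is
  deterministic, and the main performance lever.
- Fitness is evaluated against the optimum position current at the
  offspring's birth generation; the recorded mean-fitness series includes
  generation 0, and F′ is its arithmetic mean.
- Degenerate inputs: an all-zero-fitness population raises an extinction
  error; deletion with no eligible target is a recorded no-op; a basal
  decrement at b = 0 is a recorded no-op; founder search and optimum
  placement have explicit retry caps with descriptive errors.
- Known limitations: no diploidy/sex, no stochastic expression noise, no
  sequence-level binding model, no pleiotropy; the per-individual mode
  interprets "a single mutation" as at-most-one (Bernoulli per type),
  since the 10× rates remain ≪ 1.
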