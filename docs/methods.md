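# Methods

## Models

**Ring field.** The orientation column is a neural field u(x,t) on the
half-open periodic domain [−π/2, π/2), discretized on `n_grid`
uniformly spaced points with rectangle-rule quadrature. Lateral
coupling is the pure cosine w(x−y) = cos 2(x−y) (local excitation,
disynaptic inhibition at orthogonal orientations), modulated by the
presynaptic resource fraction q(x,t) ∈ (0, 1]. The gain is the
Heaviside step H(u − κ) by default; a sigmoid 1/(1+e^{−γ(u−κ)}) is
available but all analysis assumes the Heaviside limit. The bimodal
stimulus −I₀cos 4x + I_a sin 2x drives bumps at ±π/4 with peak inputs
I_R = I₀+I_a and I_L = I₀−I_a. With β = 0 the resource stays at 1 and
the model reduces to the depression-free noisy field.

**Space-free networks.** The two- and three-population networks replace
the field by firing rates u_j with cross-inhibition weighted by the
*presynaptic* population's resource (inhibition from j is q_j u_j).
Their Heaviside threshold sits at 0 (the threshold parameter κ is a
feature of the ring input geometry only); H(0) = 1 everywhere.

**Noise.** The field noise is spatially correlated with profile
⟨ξ(x,t)ξ(y,s)⟩ = ε·scale·cos(x−y)δ(t−s), realized exactly by its
rank-2 Karhunen–Loève expansion √(ε·scale)(η₁cos x + η₂sin x) with two
fresh standard normals per step. Two conventions for the coefficient
circulate for this class of models (scale = 1 and scale = π); both are
exposed through `noise_corr_scale`, default 1. Because cos(x−y) has
period 2π while the domain has length π, the correlation is *not*
periodic on the domain: noise at the two endpoints ±π/2 is
anti-correlated. The expansion implements the stated correlation
without wrapping. The space-free networks use independent white noise
of variance density ε on each activity equation (none on q); ε is a
variance density, i.e. increments are N(0, ε·dt). In the space-free
networks u_j is a firing rate and is clamped at 0 after the noise
update: without clamping, negative-rate fluctuations make the
inhibition term q_k u_k excitatory, which (because the strongest
competitor's synapses carry the largest noise gain) systematically
favors switching *back* to the previous percept and traps the
three-population network in a two-population alternation. The ring
field's u is a synaptic input, legitimately negative off-stimulus, and
is not clamped.

**Integration.** Euler–Maruyama. Desk-scale defaults: ring dt = 10⁻³
with 512 grid points (a `full_resolution()` variant restores dt = 10⁻⁴ /
2000 points); space-free networks dt = 10⁻⁴ (full resolution 10⁻⁶). A
noise-free dt-halving check keeps dominance times stable to < 0.5% at
the defaults. Non-finite states abort with the offending step index.

## Dominance detection

The right (left) percept is dominant while the activity peak over
x ∈ (0, π/2) (resp. (−π/2, 0)) is strictly larger; in the space-free
networks, while its rate is strictly larger. Ties retain the incumbent
(a measure-zero event; incumbency is the conservative convention).
Because noise makes the two peaks cross many times in quick succession
during a transition, a candidate switch is only committed once the new
leader has held its lead for `min_dwell` = 0.5 model units (5 ms),
timed at the first crossing; without debouncing the mean dominance
time is dominated by integration-step-scale flicker and does not
converge as dt → 0. The first 50 model units and the epoch in progress
at the end of burn-in are discarded; the remaining epochs tile the
interval between the first and last committed switch. Epoch durations
are reported in model units and seconds (10 ms per unit).

## Fast-slow dominance times

For τ ≫ τ_m the activity equilibrates instantly and only the resources
move. During dominance the active side's resource relaxes toward
1/(1+β) with rate (1+β)/τ (depletion βq plus recovery), and while
suppressed it recovers toward 1 with rate 1/τ. A switch occurs by
escape when the dominant side's resource reaches an escape level:

- ring, symmetric: q₀ = 2I₀√((I₀−κ)/(3I₀+κ)), from jointly solving the
  bump threshold condition and the condition that the suppressed peak
  touches threshold (the half-width at the switch satisfies
  cos 2a* = (I₀+κ)/(2I₀) and is independent of the asymmetry);
- ring, asymmetric: q_R = 2I₀(I_L−κ)/√((3I₀+κ)(I₀−κ)) and the mirror
  expression for q_L;
- two-population: q_R = I_L, q_L = I_R (cross-inhibition falls to the
  suppressed side's input);
- three-population, symmetric: the dominant resource falls to I, and
  each population is suppressed for two dominance phases per cycle.
  The next winner is always the most-recovered (longest-suppressed)
  population, which is why noise-free switching is strictly "forward".

Imposing periodicity of the resource trajectory over one cycle gives a
scalar return map whose fixed point is the dominance time. The map
always has the trivial root T = 0; a genuine relaxation oscillation is
its unique positive root, which exists iff
1/(1+β) < q_esc < (1+n)/(1+n+β) with n suppressed phases per cycle.
The solver evaluates the exact integration of this piecewise-linear
slow flow by bracketed root-finding (brentq; a 2-D quasi-Newton solve
for the asymmetric pair (T_R, T_L), seeded from the symmetric
solution). We deliberately do not transcribe any further "closed form"
on top of this: for general β the positive root is not elementary, and
the defining conditions themselves are the source of truth. Each
closed-form escape level is validated in the test suite against an
independent numerical solution of its defining system.

**Accuracy.** The adiabatic approximation carries O(τ_m/τ) corrections
from the switch transients (the loser's rate decays and the winner's
rises over a few τ_m, during which depletion continues). At τ = 50 the
analytic times agree with noise-free simulation to ≈1–2% at the slow
end of each rivalry range (ring I₀ = 0.80: 0.8%; reduced I = 0.55:
1.7%) but degrade to ≈5–10% for the fastest oscillations near the
fusion boundary (ring I₀ = 0.84: 6.6%; reduced I = 0.6: 11%); the
error shrinks roughly like 1/τ (≤1.2% at τ = 200). Tests assert both
the slow-regime accuracy and the improvement with τ.

**Upper end of the rivalry range.** The return-map existence bound
2/(2+β) (two percepts) is also what the full simulation shows: beyond
it the trajectory settles into fusion (e.g. reduced network at β = 1
fuses for I ≥ 0.65; the ring fuses for I₀ ≥ 0.9). The regime
classifier therefore labels a point "rivalry" only when the positive
root exists, which reproduces the three anchor behaviors
(winner-take-all at I₀ = 0.6, rivalry at 0.84, fusion at 1.0 for
κ = 0.5, β = 1). Where winner-take-all exists it takes priority, since
all protocols start from the winner-take-all state.

**Tristable switch ordering under noise.** Noise-free switching is
strictly forward (p_f = 1): at a switch both silent populations cross
threshold simultaneously, and the most-recovered one wins the ensuing
race because its synapses inhibit harder. This tie-break is
structurally fragile: for any ε > 0 the crossing times are jittered by
noise first-passage, and the first population to activate wins
outright (its inhibition grows two orders of magnitude faster than the
escape margin opens). The depression memory then only biases the
*mean* activation delay, so p_f drops discontinuously from 1 at ε = 0
to ≈0.55–0.65 for all ε in [10⁻⁶, 3·10⁻²] — forward switches remain
more likely than chance, and noise makes switch-backs possible, but
p_f does not decay smoothly from 1 with increasing ε in this model.

## Dominance statistics

Exponential fits use the sample mean as scale (the maximum-likelihood
estimator) and report a Kolmogorov–Smirnov distance as a sanity check.
The gamma-shaped density e^{c₁}T^{c₂}e^{−c₃T} is fitted by exact
interpolation: the histogram (Freedman–Diaconis bins, density
normalized, lightly smoothed with a coverage-normalized 3-bin moving
average — taking the raw argmax bin as the mode systematically selects
upward-fluctuating bins and biases the shape estimate) supplies the
mode T₂ (highest-density bin center; a mode in the first bin is
rejected as not gamma-peaked) and the anchors
T₂/2, T₂, 3T₂/2; taking logs makes the three anchor equations linear
in (c₁, c₂, c₃). Note the density is written with T^k rather than the
conventional T^{k−1}; the fit reports both k = c₂ and
k_conventional = c₂ + 1 (the latter is what matches the shape of
samples drawn from a standard gamma distribution). Maximum-likelihood
gamma fitting is deliberately not the default — the three-point solve
is the method under study.

The inference probability p[I_R > I_L | n cycles] is computed, by
default, by plugging the running per-percept sample means into the
exponential exceedance formula ⟨T_R⟩/(⟨T_R⟩+⟨T_L⟩) — consistent with
its asymptotic limit, since the finite-n estimator is not otherwise
pinned down. An alternative pairwise estimator (fraction of cycles
with T_R > T_L) is provided for sensitivity analysis; for exponential
marginals both share the same limit.

## Pooled protocols and problem sizes

The headline noise-driven statistics pool independent seeds at desk
scale: 16 seeds × 8000 model units (symmetric) and 22 × 16000
(asymmetric), yielding ≥500 dominance epochs per configuration and
≥200 inference cycles; the noise-free fast-slow comparison uses runs
of 8 cycles per parameter point. Seeds for replicate streams are
derived deterministically from one base seed. Identical parameters and
seed reproduce byte-identical records.

## Known limitations

- The fast-slow dominance times are leading-order adiabatic results;
  no O(τ_m/τ) transient correction is applied (see accuracy above).
- Mean dominance times under purely noise-driven switching depend
  exponentially on the effective noise variance and, at the few-percent
  level, on the debouncing convention; with the default scale = 1
  convention the symmetric noise-only configuration (I₀ = 0.9,
  ε = 0.04) yields a mean dominance time of ≈2 s at desk scale (≈0.2 s
  under scale = π). Symmetry-derived quantities (the 1/2 inference
  limit, L/R balance) are insensitive to this convention.
- Regime labels describe existence of attractors under the stated
  initial-condition priority; basins are not mapped exhaustively.
- No stability analysis beyond the existence conditions (no
  eigenvalue/Evans-function machinery), and no two-layer ocular
  architectures, traveling waves, or spatial large-deviation theory.
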