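# Methods

## The model

`imtkit` computes time-dependent charge-transfer (CT) rate coefficients
between multiple diabatic electronic states and the resulting population
dynamics after photoexcitation. The physical picture: a molecule in
solution is vertically excited from its ground state g to a bright state;
the nuclei, initially equilibrated on the ground-state surface, then relax
on the excited surface while electronic transitions to other states
(charge-transfer states, other excited states) proceed in parallel. The
collective reaction coordinate for each transition j → k is the energy gap

    U_jk(R) = V_j(R) − V_k(R)    (initial minus final, in eV),

evaluated along the nuclear trajectory. Under a Condon (constant coupling)
approximation, a classical-nuclei golden-rule treatment, and the assumption
that the instantaneous gap distribution is Gaussian with time-dependent
mean Ū_jk(t) and variance σ²_jk(t), the instantaneous-Marcus-theory (IMT)
rate coefficient is

    k_{j→k}(t) = (Γ_jk²/ħ) √(2π/σ²_jk(t)) · exp(−Ū_jk(t)²/(2σ²_jk(t))).

Equivalently, with E_r(t) = σ²(t)/(2k_BT), ΔE(t) = −Ū(t) − E_r(t) and
E_a(t) = k_BT·Ū(t)²/(2σ²(t)), the exponential is exp(−E_a(t)/k_BT). In the
long-time limit Ū → ⟨U_jk⟩_j and σ² → σ²_eq, and the expression reduces
*algebraically* to the classical Marcus rate constant

    k^M = (Γ²/ħ) √(π/(E_r k_BT)) · exp(−(ΔE+E_r)²/(4 E_r k_BT)),

with E_r = σ²_eq/(2k_BT) and ΔE = −⟨U⟩ − E_r. The package asserts this
identity to 1e-12 relative in its tests; it also fixes the sign convention
for ΔE, which we verified on the shifted-harmonic bath where
⟨U_jk⟩_j = −(ΔE + E_r) holds exactly (ΔE being the difference of the state
minima).

Populations evolve by Pauli master equations with the time-dependent
pairwise rates,

    dP_j/dt = Σ_{k≠j} [k_{k→j}(t) P_k − k_{j→k}(t) P_j].

The rates are precomputed from nuclear statistics and do not feed back on
the populations, so one rate set serves any initial electronic state.

## Nonlinear-response estimation from equilibrium trajectories

Direct evaluation of Ū(t), σ²(t) requires nonequilibrium ensembles:
initial conditions from the ground-state Boltzmann distribution, dynamics
on state j. The nonlinear-response route obtains the same moments from
*equilibrium* trajectories on state j by exponential reweighting. With
δA = A − ⟨A⟩ denoting fluctuations about the equilibrium average,

    C1(t) = ⟨δU_jk(t) e^{β δU_jg(0)}⟩ / ⟨e^{β δU_jg(0)}⟩,
    C2(t) = ⟨δU_jk²(t) e^{β δU_jg(0)}⟩ / ⟨e^{β δU_jg(0)}⟩,
    Ū(t)  = ⟨U_jk⟩ + C1(t),
    σ²(t) = ⟨U_jk²⟩ + C2(t) − Ū(t)².

This identity is exact (the ground-state density is the state-j density
times e^{βU_jg}, normalized), so the estimator is unbiased up to
finite-sample ratio effects. Implementation choices:

- **Time origins.** Averages run over trajectories and over time origins
  along each trajectory (stationarity), with a configurable origin stride
  (default: every recorded frame; dense origins are correlated, so the
  stride mainly trades cost). Because the pooled mean cancels between the
  fluctuation and the weight normalization, Ū(t) is algebraically the pure
  weighted ratio Σ w U(t₀+t)/Σ w; the code exploits this.
- **One weight set.** C1 and C2 share the denominator, so weights are
  computed once per origin from δU_jg.
- **Overflow.** β ≈ 38.7 eV⁻¹ at 300 K; exponents are shifted by their
  maximum before exponentiation (log-sum-exp).
- **Fluctuation reference.** δ-fluctuations are taken about pooled
  (all-trajectory, all-time) means; pooled means minimize bias for
  stationary equilibrium data. Per-trajectory weight normalization is
  available as an option (`per_trajectory_weights`), pooled is default.
- **Error bars.** Trajectories are split into batches (default 4, the
  common practice for this kind of data); standard errors come from a
  delete-one-batch jackknife of the pooled estimator rather than the plain
  spread of per-batch estimates. For a denominator-weighted ratio the
  jackknife tracks the random-denominator contribution that the plain
  spread misses (we measured ~10% under-coverage for the plain spread on
  replicate ensembles). Downstream moments (Ū, σ²) are jackknifed as
  complete per-replicate quantities, so the correlation between the
  equilibrium means and the TCFs propagates into their errors. For plain
  unweighted averages over independent trajectories (the nonequilibrium
  ensembles), exact moment-based standard errors are used instead.
- **Diagnostics.** The effective sample size ESS = (Σw)²/Σw² of the
  weights is always computed; an ESS fraction below a floor (default 0.05)
  logs a warning. A nonpositive estimated σ²(t) is a hard error naming the
  time point — it indicates reweighting noise, never physics, and is never
  clamped. Numerator and denominator of the TCFs are exposed separately
  for sign analysis; the estimator never symmetrizes forward/backward
  transitions (their TCF signs are data properties).

## The surrogate bath

Real applications feed the estimator with molecular-dynamics gap series;
for development and validation the package generates ensembles from an
exactly solvable bath: independent mass-weighted modes with
state-dependent shifted-harmonic potentials
V_j = Σ_i [p_i²/2 + ω_i²x_i²/2 − c_i^j x_i] + ε_j. Every gap is linear in
the coordinates, so all gap statistics are exactly Gaussian with closed
forms:

- Ū_jk(t) = Σ_i (c_i^k−c_i^j)[c_i^j/ω_i² + (c_i^g−c_i^j)/ω_i²·f_i(t)] + ε_j−ε_k,
  with f_i(t) = cos ω_i t (underdamped) or exp(−(ω_i²/γ_i)t) (overdamped);
- σ²_jk(t) = Σ_i (c_i^k−c_i^j)² k_BT/ω_i², constant in time — the harmonic
  signature that distinguishes these baths from anharmonic all-atom data,
  where the variance moves after excitation;
- E_r = Σ_i (c_i^j−c_i^k)²/(2ω_i²), satisfying σ² = 2k_BT·E_r exactly.

Propagation is analytic (harmonic rotation) or an exact
Ornstein–Uhlenbeck update (overdamped), so there is no integrator error in
oracle comparisons; the momenta are not meaningful in overdamped mode.
Units are mass-weighted (x in √eV·ps, p in √eV, c in √eV/ps), absorbing
atomic masses without loss of generality. Internally: energies in eV, time
in ps, rates in s⁻¹ (the ps⁻¹→s⁻¹ factor enters once, through ħ in eV·s).

Two canonical fixtures:

- `default_triad_model()` — four states (bright state, two CT states, an
  uncoupled ground state that only supplies initial conditions), five
  modes with 0.8–3 ps periods. Displacements are moderate
  (β²·Var(U_jg) ≈ 1), so exponential reweighting from any excited state is
  well conditioned, and couplings/offsets put the six interstate rates in
  the 1e9–1e12 s⁻¹ window — populations move on the 1–100 ps scale.
- `displaced_overdamped_model()` — donor/acceptor/ground with
  donor–acceptor E_r ≈ 0.5 eV, 3–6 ps diffusive gap relaxation, and a
  ground-state minimum displaced from the donor's. This mimics
  condensed-phase CT energetics; for it, exponential reweighting is
  hopeless by construction (β²·Var(U_jg) ≈ 12, ESS fraction ~e⁻¹²), which
  is faithful to real systems — the fixture is used through its closed
  forms and through direct nonequilibrium sampling.

What the surrogate does *not* emulate: anharmonicity (hence any time
dependence of σ²(t)), non-Gaussian gap statistics, non-Condon coupling
fluctuations, and the slow conformational heterogeneity of real solvents.
Passing tests therefore validate the estimator chain and the kinetics, not
the Gaussian/Condon assumptions themselves on real data.

## Population integration

Rates enter on a common grid in s⁻¹, are linearly interpolated inside the
grid and held at each transition's plateau value (trailing-window average,
default window one quarter of the grid) beyond its end — population
dynamics is typically integrated to 50 ps while gap statistics relax
within a few ps. The ODE system is solved with adaptive LSODA
(stiff-capable; rates across transitions can span twelve decades) at
rtol 1e-12/atol 1e-14; the generator has exact zero column sums, and total
population is conserved to better than 1e-10 over 50 ps in the tests. The
output grid is decoupled from the rate grid (dense 0.01 ps spacing for the
first 5 ps, 0.1 ps afterwards, by default). The two-state survival formula
P_D(t) = exp(−∫₀ᵗ k) uses trapezoidal quadrature on the rate grid and
agrees with the master equation with zero backward rate to 1e-6 on a
0.005 ps grid.

## Statistical design of the validation suite

The estimator-versus-oracle checks compare hundreds of correlated lag
points per run. We verified on replicate ensembles that the per-lag
z-scores (deviation over jackknife SE) are calibrated: std 1.01, no
detectable bias, near-Gaussian tails. A literal "every lag within 3 SE"
gate over ~600 comparisons would fail a correct implementation in roughly
a third of runs (the expected maximum of ~600 standard normals is ≈3), so
the suite asserts the calibrated familywise equivalent: at least 99% of
comparisons within 3 SE and all within 5 SE. Under the null this passes
with probability ≈0.997; a systematic bias of about one SE still fails.
The stochastic fixtures use one fixed seed, so the suite is deterministic.

Validation problem sizes: 2×10⁴ equilibrium trajectories of 20 ps
(0.04 ps recording), a 2 ps lag window, 0.2 ps origin stride, and 20
trajectory batches for error bars; nonequilibrium reference ensembles use
2×10⁴ direct trajectories. These sizes resolve the surrogate's relaxation
features with ~1% relative moment errors.

## Known limitations

- Classical nuclei and second-order (golden-rule) electronic coupling:
  no nuclear tunneling, no coherence, no back-reaction of the electronic
  state on the nuclei.
- The Gaussian-gap assumption is exact for the surrogate but an
  approximation for real data; strong non-Gaussianity invalidates the
  moment-to-rate map.
- Exponential reweighting degrades exponentially with β²·Var(U_jg); for
  strongly displaced ground states, direct nonequilibrium sampling is the
  only practical route, and the ESS diagnostics will say so.
- The plateau extension policy (hold the trailing average) is an
  assumption about rates beyond the sampled window; it is the natural one
  when the TCFs have visibly relaxed, and it is configurable in the data
  model.
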