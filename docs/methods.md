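# Methods

## The network model

The cascade is modelled as 19 reactions over 24 species.  Maltodextrin
is a boundary pool of glucose units (C6H10O5, concentrations in mM
glucose equivalent) attacked unit-by-unit by α-glucan phosphorylase;
chain-length distribution is not modelled.  PHB is a boundary pool of
monomer units (C4H6O2, mM monomer equivalent).  CO2 and H2O are
boundary in the stoichiometric analysis: CO2 has no consumer in the
network, so no steady state would exist with it internal, and H2O is
solvent.  All other species — the phosphorylated intermediates, the
acyl-CoA series, NADP(H), CoA and Pi — are internal, i.e. balanced
exactly at steady state.

Species carry element compositions written as neutral free-acid
formulas, with opaque moiety tokens (`CoAm`, `NADPm`) for the CoA and
NADP scaffolds plus explicit C/H/O counts for the transferable acyl and
hydride parts (NADPH is `NADPm + H2`, covering hydride and proton).
Under this convention every reaction balances C, H, O and P exactly
once H2O is written where chemistry requires it (G6PDH and FBP consume
it; the phosphoketolase reactions release it), and
`atom_balance_check` verifies this for every shipped variant.

Reversibility: the isomerases, mutase, transketolase/transaldolase,
aldolase, PTA and PhaA are reversible; αGP is reversible with a small
equilibrium constant; the two dehydrogenases, FBP, both
phosphoketolase activities, PhaB and PhaC are irreversible.  This
matches the strongly exergonic character of those steps and lets the
transketolase-2 reaction run net backwards in the XPK pathway mode
(signed flux −2).

### Variant networks

`xpk_only` / `fpk_only` remove one phosphoketolase activity each;
`xpk_essential` and `fpk_essential` additionally remove the seven
carbon-rearranging booster enzymes (TK, TIM, ALD, FBP, TAL, RPI, and
PGI or RPE respectively).  The essential variants cannot balance all
pools: the XPK-essential route over-produces NADPH 3:1 and exports G3P,
and both routes consume Pi without regenerating it.  A steady-state
mode therefore exists only if the dead-end species are re-designated
boundary — G3P, NADP+, NADPH and Pi for `xpk_essential`; E4P, Ru5P and
Pi for `fpk_essential` (NADP(H) stays internal there, and that closure
is precisely what forces the 40 % yield).  How the original analysis
balanced these pools is not documented anywhere we could consult; this
designation is the package's own choice and reproduces the 50 %/40 %
essential-pathway yields with zero moiety (scaffold) creation.

## Elementary flux modes

Modes are enumerated by the classical tableau / double-description
algorithm on the pointed cone `{v ≥ 0, S_int v = 0}` after splitting
reversible reactions, in exact integer/rational arithmetic with a
support-minimality filter at each step, then recombined into signed
fluxes; reversible-only cycles appearing twice with opposite sign are
reported once (first reaction in network order positive).  Output
ordering is lexicographic by support, so results are deterministic.
The implementation is cross-checked in the test suite against an
independent brute-force oracle (nullspace rank test over all reaction
subsets) on a battery of hand-written and randomly generated small
networks.

Yields are derived from the boundary net exchange of a mode: molar
yield = 100 × PHB flux / glucose-unit consumption; carbon yield is
exactly 2/3 of it (4 of 6 carbons).  Percentages are displayed to one
decimal with half-up rounding; exact rationals are kept internally.

## Rate laws

The study names its kinetic functions only by number, so this package
uses standard law families with the right qualitative limits:

* irreversible Michaelis–Menten, product-free:
  `v = Vmax · Π_s (S/(Km_s+S))^|a|`;
* reversible rapid-equilibrium random law:
  `v = Vmax/ΠKm_s · (ΠS − ΠP/keq) / (Π(1+S/Km_s) + Π(1+P/Km_p) − 1)`,
  zero exactly at the thermodynamic equilibrium ratio and reducing to
  the familiar uni-uni and bi-bi forms;
* the PHB-synthase law: Michaelis–Menten times a binding factor
  `C_bind/(C_bind + PHB^n)`; at `C_bind = 1000, n = 1` and PHB = 0 it
  is plain Michaelis–Menten.

Stoichiometric multiplicity enters as powers (PhaA condenses two
acetyl-CoA).  H2O is excluded from the kinetic state; CO2 is dynamic
with no consumer.  Internal time unit is minutes, matching Vmax in
mM/min (≡ U/mL enzyme loading at the 1:1 conversion); reports are per
hour.

## The stop event

Experimentally the phosphorylase stalls once maltodextrin is shortened
to maltose, at roughly 60 % consumption.  The simulation therefore
carries a terminal event at 40 % residual substrate (configurable),
located by root-finding.  At the event, substrate phosphorolysis is
switched off and maltodextrin clamped; the downstream reactions keep
running to `t_end`, draining the intermediate pools into PHB.  This
reading — "consumption ceases" rather than "the whole state freezes" —
is the package's design choice: it is the only one under which the
final titer can reach the stoichiometric expectation for the consumed
substrate (4/3 × 60 = 80 mM on the standard load), and both the titer
at the event and at `t_end` are reported so the distinction stays
visible.

## Parameter sets (synthetic stand-ins)

The fitted parameter values of the original study are not available to
this package, so the three shipped sets are clearly-labelled synthetic
stand-ins constructed from the study's narrative, fixed once:

* **model0** — the unfitted baseline: every Km 0.1 mM (except αGP's
  substrate terms, set at literature magnitude: 5 mM for glucose units,
  1 mM for Pi), binding law at `C_bind = 1000, n = 1`.  keq values are
  config inputs of literature magnitude (e.g. PGM 17, PGI 0.3, TIM 22
  toward DHAP, PTA 60, PhaA 4 × 10⁻⁵ for the thermodynamically uphill
  thiolase); computing them is outside this package's scope.
* **model1** — the first calibration round, lowering the substrate Km
  of the phosphoketolase and transketolase activities (raising the
  attainable titer) and then of PTA and PhaB (raising the rate), with
  PhaA Km at acetyl-CoA-pool scale.
* **model2** — the second round, touching only the αGP keq (0.2 → 0.05,
  less favorable phosphorolysis on shortened dextrins) and the PhaC
  binding coefficient (1000 → 400, stronger product binding).

model0 drastically underpredicts titer, rate and consumption — the
qualitative signature the calibration is meant to remove — while
model1 completes the standard 240-min run.  Conservation of carbon and
of the NADP/CoA/phosphate moieties along every trajectory is enforced
to ≤ 10⁻⁶ relative drift in the tests (LSODA, rtol 1e-8, atol 1e-10
defaults; tiny negative excursions below −1e-9 mM are rejected, smaller
ones clipped to zero).

## Enzyme-loading optimization

One-at-a-time Vmax scans, with the bifunctional groups moved together
(XPK:FPK at 1:0.12, reflecting the measured activity ratio of the
bifunctional phosphoketolase; TK1:TK2 at 1:1).  A round has two
phases: the synthase is scanned on final titer over a long horizon
(240 min round 1, 480 min round 2) and fixed at its optimum; every
other enzyme is then scanned on the initial PHB production rate (PHB
formed in the first hour) over 60 min.  The accepted optimum is the
smallest grid value reaching ≥ 99 % of the grid's best metric.  Grid
steps default to 1 mM/min; scans never mutate the shared parameter set.

## Calibration

Bounded least squares (trust-region reflective, log-space parameters,
seeded multistart) over exactly the parameter families adjusted per
round: Km entries of PKL/TK/PTA/PhaB plus the PhaC binding parameters
in round 1, additionally the αGP keq in round 2.  Each dataset carries
the enzyme loading it was measured at (`vmax_overrides`), which is an
experimental given, not a fitted quantity.  Replicate means are
fitted; SDs are reporting-only.  The loss scales residuals by the
maximum observed mean per observable per dataset.  The fit never
returns a point worse than its start.

## Synthetic data

Ground truth is a model trajectory sampled at assay-like times
(default 0–24 h, denser early); triplicate noise is multiplicative
Gaussian with CV 2 % and a 0.1 mM absolute floor, truncated at zero,
matching the magnitude of the printed experimental scatter
(fractions of a mM on ~75 mM titers).  Zero-truth samples (e.g. PHB at
t = 0) read exactly zero — there is no analyte peak to scatter — so
truncation events stay rare and are counted in the provenance along
with the seed and generating parameters.  What the generator does not
emulate: enzyme inactivation over time, substrate inhibition at high
maltodextrin, mass-transfer effects of the insoluble product, or any
systematic assay bias.  Passing calibration tests on this data
therefore demonstrate correctness of the estimation machinery, not
that the model captures every feature of real reactions.

## Problem sizes and numerical choices

The default test and acceptance computations run the full 19-reaction
network at 240–480 simulated minutes on a 1-min reporting grid, scans
on 2–10-point grids, and calibration exercises on a two-enzyme cascade
at study-scale concentrations (100 mM substrate, ~1 mM/min rates)
plus a capped-iteration round-1 emulation on the full network — sizes
chosen so the whole suite is a desk-scale computation.  Ties in the
optimal-Vmax rule cannot occur (smallest qualifying grid value);
degenerate inputs (zero consumption, zero reference flux, empty free
set, trajectories shorter than the rate window) raise explicit errors
rather than returning silent defaults.

## Known limitations

* The 4GT/PPGK second reaction step and fed-batch substrate additions
  are supported only as simulation plumbing (timed additions); they are
  not part of the calibrated model.
* Temperature/pH dependence, enzyme inactivation and substrate
  inhibition of αGP are not modelled.
* The shipped parameter sets are narrative-constructed stand-ins; any
  quantity that depends on the exact fitted values of the original
  models (rather than on stoichiometry, the stop event, or law
  structure) should be read as illustrative.
* Elementary-mode enumeration is exponential in the worst case; it is
  instantaneous on this cascade but the implementation targets
  networks of this size, not genome-scale models.
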