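# Methods

## The model

`spermsim` is a discrete-time (1 h), two-dimensional agent-based model of
germ-cell development on one cross-section of the adult mouse seminiferous
tubule. The cross-section is a circular lattice of 13 µm × 13 µm
micro-compartments (one compartment fits the largest cell, the pachytene):
tubule radius 14 compartments (~180 µm), central lumen radius 4 (~50 µm).
Ten Sertoli-cell nuclei are static obstacles on the basement ring at equal
angles; five basement compartments, interleaved between them, mark
proximity to the interstitium and remain accessible. Each compartment holds
one germ cell, except that two spermatids (round or elongated, in any
combination) may share one.

Ten germ-cell types are agents: spermatogonial stem cell, differentiating
spermatogonium (collectively A1–B), preleptotene, leptotene, zygotene,
pachytene, diplotene, secondary spermatocyte, round spermatid, elongated
spermatid. Every behaviour runs on an integer hourly timer; a behaviour
whose timer has expired but whose preconditions fail (no free neighbour,
feedback gate closed) stays pending and is retried each hour. Within one
hour each agent, visited in a fresh random permutation, executes its
pending events in the fixed order **division → death → movement →
differentiation → release**.

* **Division.** A daughter occupies one of the eight Moore neighbours;
  division fails (and is retried) if no admissible neighbour is free.
  Stem cells divide asymmetrically (one stem + one differentiating
  spermatogonium) and only while the preleptotene feedback gate is open:
  the current preleptotene count ≥ `preleptotene_threshold` (default 5).
  Preleptotenes act here as the proxy source of retinoic acid that
  licenses spermatogonial differentiation; this delayed negative/positive
  feedback loop is what makes the system oscillate with the cycle period.
  Differentiating spermatogonia divide symmetrically up to
  `spg_mitosis_rounds` (default 3) on-section rounds; daughters inherit
  the clone's remaining differentiation deadline, so a whole clone enters
  meiosis together. Diplotene → two secondary spermatocytes (meiosis I;
  the first daughter replaces the parent in place, the second needs a free
  neighbour). Secondary → two round spermatids (meiosis II; the second
  spermatid may co-occupy the parent compartment, so meiosis II never
  blocks).
* **Death.** Every non-stem type carries a lifespan drawn uniformly from
  `[lifespan_min, lifespan_max]` at type entry; the cell is removed when
  it expires. Stem cells are immortal (division alone controls their
  number, which therefore never changes).
* **Movement.** One compartment per hour, greedy within the type's radial
  position domain: stem cells minimise distance to the nearest
  interstitial marker, differentiating spermatogonia minimise |Δradius|
  (horizontal drift along the basement membrane), all other types minimise
  radius (toward the lumen). Ties break uniformly at random; a blocked
  cell stays and retries.
* **Differentiation.** In-place transitions diff_spg → preleptotene →
  leptotene → zygotene → pachytene → diplotene and round → elongated
  spermatid, each on its timer, with fresh timers and a fresh lifespan for
  the new type. Stem, diplotene and secondary develop by division only;
  the elongated spermatid is terminal.
* **Release.** An elongated spermatid matures for `release_delay` hours
  (this interval also absorbs the transient basement-ward excursion of
  real elongated spermatids, which is not modelled spatially); once mature
  and adjacent to the lumen it is released and counted as sperm.

The simulation starts at Stage I of the cycle: stem cells, differentiating
spermatogonia, pachytenes, round and elongated spermatids scattered
uniformly at random inside their position domains. Cohort timers are
phase-consistent — each seeded cohort carries the time remaining in its
current stage according to the timer chain — so the first cycle is already
synchronised. The cycle anchor used everywhere is the preleptotene onset
(entry to stage VII).

## Timer chain and the cycle

The feedback loop sets the period: a preleptotene onset licenses a stem
division burst one hour later; the new spermatogonial clone differentiates
`differentiation_time[diff_spg]` (205 h) after birth, producing the next
onset. Period = 205 + 1 = 206 h ≈ 8.6 days. The downstream onsets implied
by the chain (phase 0 = preleptotene onset): leptotene 44, zygotene 74,
pachytene 112, diplotene 74 (next cycle), secondary 100, round spermatid
112, elongation 44, release ≈ 34–44. This places the stage groups at
VII–VIII [0, 44), IX–X [44, 74), XI [74, ~104), XII [~104, 112), I–VI
[112, 206), matching the defining cell associations (e.g. at stage IX all
round spermatids have just elongated and leptotenes have appeared).

At the printed 88 h spermatogonial division time, two mitotic rounds fit
into the 205 h clone lifetime (divisions at +88 and +176), giving clones
of up to 4 cells; the canonical maximum of 3 rounds (8 cells, hence
4·2³ = 32 potential sperm per stem division) is reached only when division
is accelerated to ≤ ~68 h — which is exactly why the accelerated
contraceptive-rescue scenario produces more progeny. The transit sum from
clone birth to release is 205 + 44 + 30 + 38 + 168 + 26 + 12 + 138 + 196 =
857 h ≈ 35.7 days ≈ four cycles.

## Parameters

29 scalars form the sensitivity registry: 4 division times (stem 190,
diff_spg 88, diplotene 26, secondary 12 h), 6 differentiation times
(diff_spg 205, preleptotene 44, leptotene 30, zygotene 38, pachytene 168,
round spermatid 138 h), 18 lifespan bounds, and the initial stem count
(10). Outside the registry: the feedback threshold (5), the mitosis-round
cap (3), the release delay (196 h), the geometry, the position-domain
table (stem/diff_spg 13–14, preleptotene 12–14, leptotene/zygotene 10–13,
pachytene/diplotene/secondary 8–12, round 5–9, elongated 4–6 compartments)
and the Stage-I seeding counts (10/20/30/100/90).

Three values are anchored to published perturbation baselines:
preleptotene differentiation 44 h, spermatogonial division 88 h, feedback
threshold 5. Everything else is **calibrated**: the timer chain was laid
out to reproduce the stage-onset phases above, and the lifespan windows
were then tuned (once, before freezing) so that a long baseline run
reproduces the published cycle statistics — period 8.6 d, transit 35 d,
all 12 stages per cycle in order, sustained cycling, and a per-cycle
sperm-production success rate averaging ~23% with a 17–28% range. Each
lifespan window `[d + ~−3, d + ~40]` around its stage duration `d` implies
a per-stage death probability of roughly 5–10%, which compounds along the
pipeline to the observed ~50% loss relative to the 16-cell realised clone
ceiling. `calibrate()` re-verifies these constraints (check mode) and
offers a small coordinate-descent search over the non-anchored timers.

The initial stem count of 10 gives spermatogonial clones of ~40 cells per
burst — large enough that the threshold of 5 preleptotenes is reached
every cycle, small enough that the vitamin-A-deficiency threshold of 50 is
never reached (a structural requirement of that phenotype).

## Scenarios

* **VAD** — threshold 5 → 50 from t = 0. No stem division ever fires; the
  seeded cohorts flush through: spermatogonia/preleptotenes/leptotenes/
  zygotenes in cycle 1 only, meiocytes for two cycles, three round/
  elongated-spermatid peaks, four sperm peaks, complete clearance of
  developing cells in four cycles with the stem pool untouched.
* ***Stra8* loss** — preleptotene differentiation 44 → 93 h, beyond the
  preleptotene lifespan window (41–82 h), from a Stage I containing only
  spermatogonia: every preleptotene dies before progressing, nothing
  beyond the preleptotene/leptotene stage ever appears, yet preleptotene
  cohorts still appear each cycle and keep licensing stem divisions, so
  the cycle persists.
* **WIN 18,446** — transient retinoic-acid-synthesis block, modelled as
  quiescence of the spermatogonial compartment (stem + differentiating
  spermatogonia: all timers frozen, no events) for 8 days from day 5.
  This was a genuinely open design point: an alternative mechanism —
  forcing only the feedback gate closed while timers keep running — was
  implemented first and rejected, because the gate reopens while
  preleptotenes are still present and merely delays the next burst by
  ~14 h, producing neither the published missing cycle nor the
  post-treatment morphologies; and if the gate fully misses a preleptotene
  window the depth-1 feedback pipeline deadlocks permanently, contradicting
  the observed recovery. Spermatogonial quiescence shifts the frozen
  clone (and every later burst) by exactly the treatment duration,
  yielding exactly one missing cycle for an 8-day arrest (and
  proportionally more for 16/24/32 days), guaranteed recovery, absence of
  preleptotenes and leptotenes one day post-treatment, and at 26 days a
  stage-VII picture with a thick round-spermatid layer and no elongated
  spermatids (the missing cohort's gap travelling down the pipeline).

  One published WIN feature is *not* reproduced at the shipped densities:
  the transiently elevated progeny count of the first post-treatment
  cycle. That effect requires baseline division/movement success to be
  strongly space-limited so that the emptied epithelium helps; at the
  calibrated occupancy (~60%, with ~7% meiosis-I blocking) the
  contact-inhibition relief is smaller than the between-seed noise. The
  corresponding assertion in the acceptance test is expected to fail and
  documents this limitation.

## Sensitivity analysis

Latin hypercube sampling (scipy's `qmc.LatinHypercube`) draws 300 vectors
over the 29 parameters — timers and the stem count in 0.5–1.5× of
baseline, lifespan bounds between 0.5× the minimum and the maximum (pairs
sampled out of order are swapped). Each vector is simulated three times
for one baseline cycle (206 h) from Stage I; the output per cell type is
the time-averaged count, averaged over replicates. PRCC is computed from
the precision matrix of the rank-transformed design (with a 1e-12 ridge so
the noiseless-monotone limit stays at ±1), with two-sided Student-t
p-values on n − 2 − (K − 1) degrees of freedom; significance is p < 0.005.
Rank ties use average ranks. The strongest effects (|PRCC| > 0.33) are the
initial stem count (+~1 on the stem population, propagating downstream),
the differentiation times of spermatogonia and pachytenes, the diplotene
division time and the spermatogonial/pachytene lifespan bounds — i.e. the
timers that gate cohort hand-off. A tail of weaker but mechanically real
self-dwell effects (a type's own stage-duration parameters versus its own
mean count, |PRCC| ≈ 0.17–0.35) also clears p < 0.005 at n = 300, so the
total count of significant parameters (21) is larger than a threshold at
|PRCC| ≳ 0.3 would give.

## What the simulation does and does not emulate

The generator *is* the study system: there are no external data inputs.
Synthetic baseline runs reproduce the cyclic 12-stage composition, the
radial layering (spermatogonia and preleptotenes basal; leptotene →
pachytene progressively inward; diplotenes/secondaries closer still;
spermatids innermost), cohort-to-cohort fluctuation of counts and sperm
output, and the four-cycle transit. Not represented: individual
undifferentiated spermatogonial subtypes (A-paired/A-aligned), the three
off-section spermatogonial divisions (hence a 16-cell on-section clone
ceiling at baseline against the canonical 32), Sertoli cytoplasm,
hormones/cytokines, nuclear morphology, the explicit basement-ward
excursion of elongating spermatids, and any 3D/wave structure along the
tubule. Passing tests therefore validate the mechanism and its published
phenomenology, not quantitative agreement with any particular animal's
cell counts.

## Numerical and implementation choices

* Integer hour clock; all timers integers; a timer set to T fires T hours
  later. Simultaneous expiries resolve by the global event order (a cell
  due to divide and die the same hour divides first).
* Single `random.Random(seed)` stream drives everything (placement,
  permutation, lifespan draws, tie-breaks); identical
  (parameters, seed, scenario) give bit-identical runs across platforms.
* Agent iteration order is a fresh uniform permutation each hour to avoid
  spatial sweep bias. Newborn daughters act from the next hour.
* Circle membership: lumen `d < r_lumen`, epithelium `r_lumen ≤ d ≤ R`,
  Euclidean distance between compartment centres. Sertoli nuclei at ring
  radius R − 0.6, angles 2πk/10; interstitial markers at the half-spacing
  offset so the two never collide.
* Per-cycle accounting consolidates preleptotene-onset anchors closer than
  0.6× the median spacing (a space-delayed clone occasionally fires a
  brief second onset inside one cycle).
* Simulation sizes in the shipped tests and the acceptance script: three
  29-cycle baseline runs (20 scored cycles after a 4-cycle warm-up) for
  the success-rate band, period, transit and staging; five seeded 8-cycle
  pairs for the contraceptive scenario; the full 300 × 3 design for
  sensitivity (the test suite uses a 100-sample smoke version with
  sign-pattern checks).

## Known limitations

* The supplementary parameter tables of the original study are not
  public; all non-anchored defaults are this package's own calibration and
  will not match the original values number-for-number. Stochastic
  acceptance bands (success rate, period, transit) are the meaningful
  comparison.
* The WIN post-treatment efficiency boost and the exact count of
  significant sensitivity parameters depend on the original's crowding
  and noise structure and are not reproduced (see above).
* Stage sub-indices within composition groups (e.g. II vs V) are assigned
  by equal time-subdivision since group entry; only group boundaries are
  composition-defined.
* Movement is greedy with random tie-breaks rather than probabilistic; a
  `random_move_prob` hook exists (default 0) but is not part of the
  calibrated baseline.
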