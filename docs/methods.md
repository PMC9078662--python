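# Methods

## The screening model

The screen compares a compound's HPLC peak area across three
incubation conditions of the same extract.  Ultrafiltration retains
two pools of a compound: the fraction bound to the enzyme preparation,
and a non-specific fraction adsorbed to the membrane.  The blank run
(no enzyme) isolates the second pool, so the ratio `S/N = A_a/A_b`
exceeds 1 exactly when the enzyme pool binds the compound, and
`S-S/N = (A_a − A_c)/A_b` exceeds 0 exactly when pre-blocking a
target's active site with a competitive probe released part of that
binding.  Both criteria are applied as strict inequalities on the
computed ratios; boundary values fail.  A compound absent from the
blank run (`A_b = 0`) has no defined ratio and is reported as
`not evaluable` rather than scored — the screen cannot distinguish
infinite enrichment from a detection failure.  Single-replicate areas
are treated deterministically; no uncertainty is attached to ratios.

## Peak processing

All traces are uniformly sampled; time is minutes, signal mAU, area
mAU·min.  Non-uniform grids are rejected rather than resampled.

**Baseline.** Morphological opening — a rolling minimum followed by a
rolling maximum over the same window (default 2.0 min) — then a
rolling mean, computed on a trace pre-smoothed over 1/8 window.  The
opening erases peaks narrower than the window while following linear
drift without lag; the pre-smoothing keeps the floor from riding the
extremes of the detector noise, whose depth would otherwise vary with
local peak coverage; odd-reflection padding preserves drift slopes at
the run edges.  The window must exceed the widest peak's full base
width (≈ 8 peak sigma), or the baseline starts climbing into peaks.
Every filter is local, so the baseline under one peak never depends on
distant parts of the trace — a property the tie-handling below relies
on.

**Noise.** `1.4826 · median(|Δsignal|)/√2` on the baseline-subtracted
trace: first differences cancel the slowly varying peak component, the
median absorbs the sparse large differences on peak flanks, and the
constants rescale the median absolute difference of Gaussian noise to
its standard deviation.

**Detection.** Local maxima of the residual smoothed over 5 samples,
with height and prominence at least `min_snr` (default 5) times the
noise level.  The prominence floor suppresses the duplicate maxima
noise creates on one peak's top.  Reported bounds extend from the apex
to the nearest flanking local minimum — recognised only after the
trace climbs one noise-sd back out of it — or to the first sample
below one noise-sd, whichever comes first.

**Integration.** The reported area integrates the residual over a
fixed radius of ±3σ̂ around the apex, where σ̂ comes from the
half-height width of the smoothed peak, minus a local baseline offset
(25%-trimmed mean of the residual in two guarded ~2-min flanking
windows), divided by erf(3/√2) to restore the 0.27% of a Gaussian
outside ±3σ.  This construction has two properties the valley-bounded
trapezoid lacks: its truncation error is the same *fraction* of every
Gaussian peak regardless of height, so it cancels exactly in area
ratios; and it depends only on the trace near the peak, so two runs
that agree around a compound's retention time yield identical areas
(areas are reported at 1 nAU·min resolution to keep last-bit filter
arithmetic from breaking such ties).  Exact ties matter because the
classification criteria are strict inequalities: a non-binder has
`S/N = 1` and a purely allosteric binder has `S-S/N = 0` *by
construction*, and any asymmetric numerical jitter would resolve those
boundary cases by coin flip.  The standalone `integrate_peak` performs
the plain clipped trapezoid over caller-supplied bounds.

Co-eluting peaks are not deconvolved; panels whose reference retention
times sit closer than twice the matching tolerance are rejected.  The
matcher assigns, per run and compound, the in-tolerance peak nearest
the reference retention time (ties toward earlier elution, default
tolerance 0.2 min), never assigns a peak twice, and scores missing
peaks as area 0.

## The simulator

The incubation is modelled at equilibrium — the endpoint of a 60-min
37 °C incubation — as mass-action competition.  Each enzyme exposes
two independent saturable site pools of capacity equal to its total
concentration: the orthosteric site, where the competitive probes and
competitively-inhibiting ligands bind, and an allosteric site for
ligands known to bind elsewhere (a deliberate simplification of
non-competitive inhibition that reproduces its screening signature:
binding that survives the probe block).  Free-site concentrations are
solved by damped fixed point (damping 0.5, relative mass-balance
residual < 1e-12, at most 10 000 iterations), with free ligand
eliminated analytically from each ligand's mass balance; a single
ligand–enzyme pair reduces to the binding quadratic, which serves as
the independent test oracle.

The retained amount of ligand *i* is `Σ_j bound_ij + ν_i·total_i`,
with the membrane-retention fraction ν condition-independent — this is
precisely the assumption under which the blank run measures
non-specific retention.  Peak area is the retained amount times a
per-ligand response factor.  Chromatograms are sums of Gaussian peaks
(areas from the equilibrium, widths equal within a run) plus linear
drift and i.i.d. Gaussian detector noise.

Noise is drawn **once per dataset** and shared by all runs of a
screen (a paired design).  The runs of one screen are consecutive
injections on one instrument, and the screen's statistics are
*within-compound contrasts* across runs; pairing the noise makes equal
true areas integrate to equal measured areas, so the strict criteria
resolve boundary cases (non-binders, allosteric binders) by
construction rather than by the sign of independent noise.  The seed
therefore changes the noise realisation but never the true areas.

What the simulator does *not* emulate: retention-time drift between
runs, asymmetric (tailing) peaks, co-elution, detector saturation,
compound-dependent peak widths, and probe peaks in the chromatogram.
Passing tests therefore demonstrate correctness of the computational
chain under idealised chromatography, not robustness to real
instrument artefacts.

### Default study conditions

* grid 0–105 min at 0.01 min (the synthetic detector's sampling of a
  105-min gradient), peak σ 0.15 min, drift 2 mAU over the run, noise
  0.05 mAU;
* enzyme totals ~1 μM, ligand totals 1–10 μM (a 0.1 mg/mL extract),
  membrane retention ν ≈ 0.1, probes in large excess at 100–1000×
  their Kd (probe Kd default 0.1 μM, a placeholder — published Kd
  values for the three probes are not available).

### The packaged worked example

`danshen4` encodes the published tanshinone screen directly at the
area level: every compound's blank area is normalised to 1.0 mAU·min
and the experimental/control areas are set to the published S/N and
S-S/N via `A_a = S/N·A_b`, `A_c = (S/N − S-S/N)·A_b`.  Retention
times (78.4, 84.1, 88.9, 96.2 min), six equal-area background peaks,
peak width and noise level are package choices — the original study
published ratios, not raw chromatograms.  The dataset's defined seed
is 1.

## Problem sizes used in the checks

The worked-example pipeline runs on 5 × 10 500-sample chromatograms.
Solver correctness uses 100 random single-pair systems against the
quadratic and 30 random multi-ligand/multi-enzyme systems for mass
balance; integration accuracy uses 40 random Gaussians (σ from 0.05 to
0.4 min); specificity recovery uses 20 seeded replicates of a
two-enzyme, three-ligand screen on a 26-min grid.  The complete suite
runs in well under a minute.

## Known limitations

* Constant-tolerance retention matching: no warping or alignment.
* The allosteric pool is independent of the orthosteric pool; real
  non-competitive inhibition can be cooperative in either direction.
  The model cannot produce `S-S/N < 0` (probe blocking can never
  *increase* a simulated ligand's binding), although the worked
  example encodes such negative values directly at the area level.
* `S-S/N` for a displaced ligand depends on probe excess; with probes
  below ~10× their Kd, orthosteric ligands may fall under the
  detection criteria even though binding is genuine.
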