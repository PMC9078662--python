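"""Synthetic screens: competitive-binding equilibria and chromatograms.

The ultrafiltration screen retains, for each compound, the amount bound
to the enzyme pool plus a non-specific fraction stuck to the membrane;
HPLC then reports that retained amount as a peak area.  This module
models the incubation as a mass-action equilibrium:

* each enzyme carries two independent saturable site pools of equal
  capacity -- the orthosteric (active) site the competitive probes
  occupy, and an allosteric site for ligands that bind elsewhere;
* every ligand binds a given enzyme at one site class with a
  dissociation constant Kd, competing with all other occupants of that
  site pool (including the probe, for orthosteric ligands in a
  control incubation);
* the membrane additionally retains a condition-independent fraction
  ``nu`` of each ligand's total, which is exactly what the blank run
  measures.

Peak area is proportional to the retained amount through a per-ligand
response factor, so the model truth of the screening ratios is

    S/N     = 1 + sum_j bound_ij / (nu_i * total_i)
    S-S/N_j = (A_a - A_c_j) / A_b

and a ligand is truly specific for enzyme j exactly when it binds j
orthosterically.  Chromatograms are sums of Gaussian peaks over a
uniform grid with linear drift and i.i.d. Gaussian detector noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .chrom_model import (
    Chromatogram,
    ScreenDesign,
    ValidationError,
    write_chromatogram,
    write_design,
)
from .peakproc import CompoundPanel, write_panel

__all__ = [
    "Enzyme",
    "Ligand",
    "Probe",
    "BindingSystem",
    "EquilibriumState",
    "ORTHOSTERIC",
    "ALLOSTERIC",
    "closed_form_pair",
    "solve_equilibrium",
    "simulate_retentate",
    "synthesize_chromatogram",
    "generate_screen_dataset",
    "danshen4_fixture",
    "DANSHEN4_AREAS",
    "DANSHEN4_RTS",
]

ORTHOSTERIC = "orthosteric"
ALLOSTERIC = "allosteric"


@dataclass(frozen=True)
class Enzyme:
    enzyme_id: str
    total_conc: float  # uM

    def __post_init__(self):
        if self.total_conc < 0:
            raise ValidationError("enzyme concentration must be non-negative")


@dataclass(frozen=True)
class Ligand:
    """One extract compound.

    ``response_factor`` converts retained amount (uM) to peak area
    (mAU*min); ``nonspecific_fraction`` is the membrane-retained
    fraction measured by the blank run; ``reference_rt`` places the
    compound's peak on the chromatogram, minutes.
    """

    ligand_id: str
    total_conc: float  # uM
    response_factor: float = 1.0  # mAU*min per uM retained
    nonspecific_fraction: float = 0.1
    reference_rt: float = 0.0

    def __post_init__(self):
        if self.total_conc < 0 or self.response_factor < 0:
            raise ValidationError("ligand concentrations must be non-negative")
        if not 0 <= self.nonspecific_fraction < 1:
            raise ValidationError("nonspecific_fraction must lie in [0, 1)")


@dataclass(frozen=True)
class Probe:
    probe_id: str
    total_conc: float  # uM
    kd: float  # uM, always orthosteric

    def __post_init__(self):
        if self.total_conc < 0:
            raise ValidationError("probe concentration must be non-negative")
        if self.kd <= 0:
            raise ValidationError("probe Kd must be positive")


@dataclass(frozen=True)
class BindingSystem:
    """Ligands, enzymes, probes, and their pairwise binding parameters."""

    enzymes: tuple[Enzyme, ...]
    ligands: tuple[Ligand, ...]
    kd: Mapping[tuple[str, str], float]  # (ligand, enzyme) -> Kd, uM
    site: Mapping[tuple[str, str], str]  # (ligand, enzyme) -> site class
    probes: Mapping[str, Probe]  # enzyme -> probe

    def __post_init__(self):
        object.__setattr__(self, "enzymes", tuple(self.enzymes))
        object.__setattr__(self, "ligands", tuple(self.ligands))
        object.__setattr__(self, "kd", dict(self.kd))
        object.__setattr__(self, "site", dict(self.site))
        object.__setattr__(self, "probes", dict(self.probes))
        enzyme_ids = {e.enzyme_id for e in self.enzymes}
        ligand_ids = {l.ligand_id for l in self.ligands}
        if len(enzyme_ids) != len(self.enzymes) or len(ligand_ids) != len(self.ligands):
            raise ValidationError("duplicate enzyme or ligand identifiers")
        for (lig, enz), kd in self.kd.items():
            if lig not in ligand_ids or enz not in enzyme_ids:
                raise ValidationError(f"Kd entry for unknown pair ({lig}, {enz})")
            if kd <= 0:
                raise ValidationError(f"Kd must be positive for ({lig}, {enz})")
            if self.site.get((lig, enz), ORTHOSTERIC) not in (ORTHOSTERIC, ALLOSTERIC):
                raise ValidationError(f"unknown site class for ({lig}, {enz})")
        for enz in self.probes:
            if enz not in enzyme_ids:
                raise ValidationError(f"probe for unknown enzyme {enz!r}")

    def site_of(self, ligand_id: str, enzyme_id: str) -> str:
        return self.site.get((ligand_id, enzyme_id), ORTHOSTERIC)


@dataclass(frozen=True)
class EquilibriumState:
    free_enzyme: Mapping[tuple[str, str], float]  # (enzyme, site class) -> uM
    free_ligand: Mapping[str, float]  # ligand -> uM
    bound: Mapping[tuple[str, str], float]  # (ligand, enzyme) -> uM
    bound_probe: Mapping[str, float]  # enzyme -> uM


def closed_form_pair(E_T: float, L_T: float, Kd: float) -> float:
    """Bound complex concentration of a single 1:1 pair.

    Root of the binding quadratic ``b^2 - (E+L+K) b + E L = 0`` on the
    physical branch.
    """
    if E_T < 0 or L_T < 0 or Kd <= 0:
        raise ValueError("need E_T, L_T >= 0 and Kd > 0")
    s = E_T + L_T + Kd
    return (s - math.sqrt(s * s - 4.0 * E_T * L_T)) / 2.0


def _parse_condition(condition) -> tuple[str, str | None]:
    if isinstance(condition, (tuple, list)):
        kind, target = condition
        return str(kind), str(target)
    condition = str(condition)
    if condition.startswith("control:"):
        return "control", condition.split(":", 1)[1]
    if condition in ("blank", "experimental"):
        return condition, None
    raise ValueError(f"unknown condition {condition!r}")


def solve_equilibrium(
    system: BindingSystem,
    condition,
    tol: float = 1e-12,
    max_iter: int = 10_000,
) -> EquilibriumState:
    """Solve the competitive mass-action equilibrium for one condition.

    ``condition`` is ``'blank'`` (all enzyme totals set to zero),
    ``'experimental'``, or ``('control', target)`` / ``'control:target'``
    (that target's probe joins the orthosteric competition).

    Free site concentrations are iterated by damped fixed point; free
    ligand is eliminated analytically from each ligand's mass balance.
    Convergence is declared when every enzyme-site mass balance holds
    to a relative residual below ``tol``.
    """
    kind, target = _parse_condition(condition)
    if kind == "control":
        if target not in system.probes:
            raise ValidationError(f"no probe defined for target {target!r}")

    # species: ligands, plus the active probe in a control incubation
    species_ids = [l.ligand_id for l in system.ligands]
    totals = [l.total_conc for l in system.ligands]
    probe_idx = None
    if kind == "control":
        probe = system.probes[target]
        probe_idx = len(species_ids)
        species_ids.append(probe.probe_id)
        totals.append(probe.total_conc)
    totals = np.asarray(totals, dtype=float)

    # site pools: (enzyme, site class), capacity = enzyme total
    sites = [(e.enzyme_id, sc) for e in system.enzymes for sc in (ORTHOSTERIC, ALLOSTERIC)]
    caps = np.array(
        [0.0 if kind == "blank" else e.total_conc for e in system.enzymes for _ in range(2)]
    )

    # affinity matrix 1/Kd, zero where a species does not bind a site
    inv_kd = np.zeros((len(species_ids), len(sites)))
    for i, lig in enumerate(system.ligands):
        for s, (enz, sc) in enumerate(sites):
            kd = system.kd.get((lig.ligand_id, enz))
            if kd is not None and system.site_of(lig.ligand_id, enz) == sc:
                inv_kd[i, s] = 1.0 / kd
    if probe_idx is not None:
        s = sites.index((target, ORTHOSTERIC))
        inv_kd[probe_idx, s] = 1.0 / probe.kd

    free_site = caps.copy()
    damping = 0.5
    residual = np.inf
    for _ in range(max_iter):
        free_species = totals / (1.0 + inv_kd @ free_site)
        denom = 1.0 + free_species @ inv_kd
        new = caps / denom
        # enzyme-site mass balance: free*(1 + sum occ/Kd) must equal capacity
        residual = float(
            np.max(np.abs(free_site * denom - caps) / np.maximum(caps, 1e-300))
        ) if caps.size else 0.0
        if residual < tol:
            break
        free_site = (1.0 - damping) * free_site + damping * new
    else:
        raise RuntimeError(
            f"equilibrium iteration did not converge: relative residual {residual:.3e}"
        )

    free_species = totals / (1.0 + inv_kd @ free_site)
    bound_matrix = np.outer(free_species, free_site) * inv_kd  # per (species, site)

    free_enzyme = {site: float(f) for site, f in zip(sites, free_site)}
    free_ligand = {
        lig.ligand_id: float(free_species[i]) for i, lig in enumerate(system.ligands)
    }
    bound: dict[tuple[str, str], float] = {}
    for i, lig in enumerate(system.ligands):
        for s, (enz, _) in enumerate(sites):
            if inv_kd[i, s] > 0:
                bound[(lig.ligand_id, enz)] = float(bound_matrix[i, s])
    bound_probe = {}
    if probe_idx is not None:
        s = sites.index((target, ORTHOSTERIC))
        bound_probe[target] = float(bound_matrix[probe_idx, s])
    return EquilibriumState(free_enzyme, free_ligand, bound, bound_probe)


def simulate_retentate(system: BindingSystem, condition) -> dict[str, tuple[float, float]]:
    """Retained amount and true peak area per ligand for one condition.

    retained = enzyme-bound + nonspecific_fraction * total;
    area = response_factor * retained.  Non-specific membrane retention
    is condition-independent, so the blank run's area is
    ``response_factor * nu * total``.
    """
    state = solve_equilibrium(system, condition)
    out = {}
    for lig in system.ligands:
        bound = sum(
            amt for (l, _), amt in state.bound.items() if l == lig.ligand_id
        )
        retained = bound + lig.nonspecific_fraction * lig.total_conc
        out[lig.ligand_id] = (retained, lig.response_factor * retained)
    return out


# ---------------------------------------------------------------------------
# Chromatogram synthesis


def make_grid(t_end: float = 105.0, dt: float = 0.01, t_start: float = 0.0) -> np.ndarray:
    """Uniform time grid in minutes, [t_start, t_end) with step dt."""
    return np.arange(t_start, t_end, dt)


def synthesize_chromatogram(
    areas: Mapping[str, float],
    rts: Mapping[str, float],
    sigma: float,
    background: Sequence[tuple[float, float]] = (),
    noise_sd: float = 0.0,
    drift: float = 0.0,
    seed: int = 0,
    grid: np.ndarray | None = None,
    run_id: str = "run",
    group: str = "experimental",
    control_target: str = "",
) -> Chromatogram:
    """Render peak areas as a noisy chromatogram.

    Each compound contributes a Gaussian of the given area and width
    ``sigma`` centred at its retention time; ``background`` adds
    (rt, area) peaks of the same width; ``drift`` mAU accumulate
    linearly over the run; i.i.d. Gaussian noise of ``noise_sd`` mAU is
    drawn from ``seed`` (deterministic given the seed).
    """
    if grid is None:
        grid = make_grid()
    grid = np.asarray(grid, dtype=float)
    dt = grid[1] - grid[0]
    if sigma < 5 * dt:
        raise ValueError(f"sigma {sigma} min must span at least 5 grid steps ({dt} min)")
    peaks = [(rts[c], a) for c, a in areas.items()] + list(background)
    signal = np.zeros_like(grid)
    for rt, area in peaks:
        if area < 0:
            raise ValueError("peak areas must be non-negative")
        if not grid[0] <= rt <= grid[-1]:
            raise ValueError(f"retention time {rt} min outside the grid")
        if area > 0:
            signal += (area / (sigma * math.sqrt(2 * math.pi))) * np.exp(
                -((grid - rt) ** 2) / (2 * sigma**2)
            )
    if drift:
        signal = signal + drift * (grid - grid[0]) / (grid[-1] - grid[0])
    if noise_sd:
        rng = np.random.default_rng(seed)
        signal = signal + rng.normal(0.0, noise_sd, size=grid.size)
    return Chromatogram(run_id, group, control_target, grid, signal)


# Detector noise is drawn once per dataset and shared by every run (a
# paired design): the runs of one screen are consecutive injections on
# one instrument, and the screening ratios compare the same compound
# across runs, so equal true areas must integrate to equal measured
# areas.  With independent per-run noise the strict S/N > 1 and
# S-S/N > 0 criteria would turn every exact tie (non-binders, purely
# allosteric pairs) into a coin flip.


def _model_truth(system: BindingSystem, design: ScreenDesign) -> pd.DataFrame:
    """Model-truth ratios and labels implied by the binding system."""
    blank = simulate_retentate(system, "blank")
    exp = simulate_retentate(system, "experimental")
    ctl = {t: simulate_retentate(system, ("control", t)) for t in design.targets}
    rows = []
    for lig in system.ligands:
        a_b = blank[lig.ligand_id][1]
        a_a = exp[lig.ligand_id][1]
        for t in design.targets:
            a_c = ctl[t][lig.ligand_id][1]
            sn = a_a / a_b if a_b > 0 else float("nan")
            ssn = (a_a - a_c) / a_b if a_b > 0 else float("nan")
            truly_specific = (
                (lig.ligand_id, t) in system.kd
                and system.site_of(lig.ligand_id, t) == ORTHOSTERIC
            )
            rows.append(
                {
                    "compound_id": lig.ligand_id,
                    "target": t,
                    "model_sn": sn,
                    "model_ssn": ssn,
                    "true_specific": truly_specific,
                }
            )
    return pd.DataFrame(rows)


def generate_screen_dataset(
    system: BindingSystem,
    design: ScreenDesign,
    sigma: float = 0.15,
    background: Sequence[tuple[float, float]] = (),
    noise_sd: float = 0.05,
    drift: float = 2.0,
    seed: int = 0,
    grid: np.ndarray | None = None,
) -> tuple[dict[str, Chromatogram], pd.DataFrame]:
    """Simulate a full screen: one chromatogram per design run plus the
    ground-truth table of model ratios and specific-ligand labels.

    The seed controls detector noise only; the underlying equilibrium
    areas are deterministic functions of the binding system.
    """
    if set(design.targets) - {e.enzyme_id for e in system.enzymes}:
        raise ValidationError("design targets must be simulated enzymes")
    rts = {l.ligand_id: l.reference_rt for l in system.ligands}
    chroms: dict[str, Chromatogram] = {}
    for run_id, group, ctl in design.runs:
        condition = {"blank": "blank", "experimental": "experimental"}.get(
            group, ("control", ctl)
        )
        areas = {l: area for l, (_, area) in simulate_retentate(system, condition).items()}
        chroms[run_id] = synthesize_chromatogram(
            areas,
            rts,
            sigma=sigma,
            background=background,
            noise_sd=noise_sd,
            drift=drift,
            seed=seed,
            grid=grid,
            run_id=run_id,
            group=group,
            control_target=ctl,
        )
    return chroms, _model_truth(system, design)


# ---------------------------------------------------------------------------
# The Danshen worked-example fixture


#: Per-run tanshinone peak areas in mAU*min.  The blank area of every
#: compound is normalised to 1.0; experimental and control areas are set
#: so that the screen reproduces the published S/N and S-S/N ratios of
#: the four major tanshinones against CYP1A2, 2C9 and 3A4.
DANSHEN4_AREAS: dict[str, dict[str, float]] = {
    "dihydrotanshinone": {
        "blank": 1.00, "experimental": 1.16,
        "CYP1A2": 1.07, "CYP2C9": 1.23, "CYP3A4": 1.37,
    },
    "tanshinone_I": {
        "blank": 1.00, "experimental": 1.88,
        "CYP1A2": 1.84, "CYP2C9": 1.72, "CYP3A4": 1.75,
    },
    "cryptotanshinone": {
        "blank": 1.00, "experimental": 1.33,
        "CYP1A2": 0.82, "CYP2C9": 0.86, "CYP3A4": 0.79,
    },
    "tanshinone_IIA": {
        "blank": 1.00, "experimental": 2.34,
        "CYP1A2": 1.72, "CYP2C9": 1.72, "CYP3A4": 1.95,
    },
}

#: Reference retention times, minutes (late-eluting diterpenes on a
#: 0-105 min methanol gradient).
DANSHEN4_RTS = {
    "dihydrotanshinone": 78.4,
    "tanshinone_I": 84.1,
    "cryptotanshinone": 88.9,
    "tanshinone_IIA": 96.2,
}

#: Matrix peaks present at equal area in every run (rt, area).
_DANSHEN4_BACKGROUND = (
    (12.0, 0.6),
    (25.0, 1.5),
    (38.0, 0.9),
    (51.0, 2.0),
    (63.0, 1.2),
    (70.0, 0.8),
)

_DANSHEN4_TARGETS = ("CYP1A2", "CYP2C9", "CYP3A4")
_DANSHEN4_PROBES = {
    "CYP1A2": "alpha-naphthoflavone",
    "CYP2C9": "sulfaphenazole",
    "CYP3A4": "ketoconazole",
}


def danshen4_design() -> ScreenDesign:
    """Five-run design of the Danshen worked example."""
    runs = [("blank", "blank", ""), ("experimental", "experimental", "")] + [
        (f"control_{t}", "control", t) for t in _DANSHEN4_TARGETS
    ]
    return ScreenDesign(
        targets=_DANSHEN4_TARGETS,
        probe_of=_DANSHEN4_PROBES,
        runs=tuple(runs),
        chromatogram_paths={r[0]: f"{r[0]}.csv" for r in runs},
    )


def danshen4_chromatograms(
    seed: int = 1,
    sigma: float = 0.15,
    noise_sd: float = 0.05,
    drift: float = 2.0,
) -> dict[str, Chromatogram]:
    """Synthesize the five chromatograms of the Danshen fixture in memory."""
    design = danshen4_design()
    chroms = {}
    for run_id, group, ctl in design.runs:
        key = ctl if group == "control" else group
        areas = {c: DANSHEN4_AREAS[c][key] for c in DANSHEN4_AREAS}
        chroms[run_id] = synthesize_chromatogram(
            areas,
            DANSHEN4_RTS,
            sigma=sigma,
            background=_DANSHEN4_BACKGROUND,
            noise_sd=noise_sd,
            drift=drift,
            seed=seed,
            run_id=run_id,
            group=group,
            control_target=ctl,
        )
    return chroms


def danshen4_panel() -> CompoundPanel:
    return CompoundPanel(tuple(DANSHEN4_RTS.items()))


def danshen4_fixture(outdir: str | Path, seed: int = 1) -> ScreenDesign:
    """Write the Danshen worked-example fixture to ``outdir``.

    Emits the five chromatogram CSVs, the design manifest
    (``design.yaml``), the compound panel (``panel.csv``) and the
    ground-truth ratio table (``ground_truth.csv``).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    design = danshen4_design()
    for run_id, chrom in danshen4_chromatograms(seed=seed).items():
        write_chromatogram(chrom, outdir / f"{run_id}.csv")
    write_design(design, outdir / "design.yaml")
    write_panel(danshen4_panel(), outdir / "panel.csv")
    rows = []
    for compound, areas in DANSHEN4_AREAS.items():
        for t in _DANSHEN4_TARGETS:
            sn = areas["experimental"] / areas["blank"]
            ssn = (areas["experimental"] - areas[t]) / areas["blank"]
            rows.append(
                {
                    "compound_id": compound,
                    "target": t,
                    "model_sn": round(sn, 10),
                    "model_ssn": round(ssn, 10),
                    "true_specific": sn > 1 and ssn > 0,
                }
            )
    pd.DataFrame(rows).to_csv(outdir / "ground_truth.csv", index=False)
    return design
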