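"""Parameter studies: ECV sweeps, diffusivity sweeps, gradient comparison.

Each experiment enumerates (substrate, sequence, G_max, diffusivity,
realisation) combinations, runs the Monte Carlo engine with seeds
derived deterministically from one master seed, and returns tidy
pandas tables: per-realisation tensor metrics, per-combination medians
with confidence intervals and eigenvector cones, and the linear fits
the studies are about (e.g. MD versus ECV in percent).

Substrate families:

* ``cuboid`` — idealised regular cuboid lattice at each target ECV;
* ``thickened`` — synthetic-histology raster morphed *down* to the
  target ECV by cell thickening (non-uniform residual gaps);
* ``shrunk`` — the same raster thickened to its minimum-ECV fixed point
  first, then eroded back *up* to the target (uniform gaps).

The two histology-derived families reach identical ECVs with different
extra-cellular space distributions, which is the point of the
comparison.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import sequences as seqs
from .engine import RunConfig, run, seed_particles
from .geometry import extrude_block, make_cuboid_block, polygonize
from .lattice import SubstrateLattice, assemble_lattice
from .raster import (ecv_area, morph_to_ecv, synthesize_histology,
                     thicken_to_fixed_point)
from .tensor import (DiffusionTensor, SignalSet, attenuation,
                     compartment_filter, fit_tensor, realisation_stats)

__all__ = [
    "ExperimentPlan",
    "derive_seed",
    "build_substrate",
    "simulate_tensors",
    "run_ecv_sweep",
    "run_diffusivity_sweep",
    "run_gmax_comparison",
]

#: The ten extra-cellular volume fractions of the morphing study.
ECV_TARGETS_DEFAULT = tuple(np.round(np.linspace(0.16, 0.41, 10), 4))


@dataclass(frozen=True)
class ExperimentPlan:
    """Declarative description of a parameter study.

    Defaults are the full study conditions (10^4 particles, 10
    realisations, full-size synthetic histology); ``scale`` < 1 shrinks
    particle counts and realisations proportionally for quick runs
    without touching the physics.
    """

    families: tuple[str, ...] = ("cuboid",)
    ecv_targets: tuple[float, ...] = ECV_TARGETS_DEFAULT
    sequences: tuple[str, ...] = ("PGSE", "M2SE", "STEAM")
    g_max: tuple[int, ...] = (40,)
    diffusivities: tuple[tuple[float, float], ...] = ((1.5, 3.0),)
    realisations: int = 10
    n_particles: int = 10_000
    seed: int = 0
    scale: float = 1.0
    # substrate construction parameters
    roi_um: tuple[float, float] = (500.0, 400.0)
    n_sheetlets: int = 12
    sin_amplitude: float = 5.0
    rotation_rate: float = 10.0
    mean_cell_area_um2: float = 110.0

    @property
    def n_p(self) -> int:
        return max(100, int(round(self.n_particles * self.scale)))

    @property
    def n_real(self) -> int:
        return max(1, int(round(self.realisations * min(1.0, self.scale * 3))))


def derive_seed(master: int, *parts) -> int:
    """Deterministic sub-seed (< 2^31) from a master seed and labels."""
    h = hashlib.sha256(repr((int(master),) + parts).encode()).digest()
    return int.from_bytes(h[:4], "little") & 0x7FFFFFFF


def _hash_array(a: np.ndarray) -> str:
    return hashlib.sha1(np.ascontiguousarray(a).tobytes()).hexdigest()[:12]


def build_substrate(plan: ExperimentPlan, family: str, ecv: float
                    ) -> SubstrateLattice:
    """Construct the lattice for one (family, target ECV) combination."""
    if family == "cuboid":
        block = make_cuboid_block(mean_area=plan.mean_cell_area_um2,
                                  target_ecv=ecv)
        return assemble_lattice(block, rotation_rate=plan.rotation_rate)

    gen_seed = derive_seed(plan.seed, "histology")
    base = synthesize_histology(target_ecs=0.40, roi_um=plan.roi_um,
                                n_sheetlets=plan.n_sheetlets,
                                mean_cell_area_um2=plan.mean_cell_area_um2,
                                seed=gen_seed)
    if family == "thickened":
        raster = morph_to_ecv(base, ecv, seed=derive_seed(plan.seed, "morph"))
    elif family == "shrunk":
        rmin, _ = thicken_to_fixed_point(base)
        if ecv_area(rmin) > ecv:
            raise ValueError(
                f"minimum reachable ECV {ecv_area(rmin):.3f} exceeds "
                f"target {ecv:.3f}")
        raster = morph_to_ecv(rmin, ecv, seed=derive_seed(plan.seed, "morph"))
    else:
        raise ValueError(f"unknown substrate family {family!r}")
    # one extrusion seed for every family: morphs of the same tissue
    # must differ only in their 2-D ECS distribution, not in the drawn
    # cell lengths/offsets
    block = extrude_block(polygonize(raster),
                          seed=derive_seed(plan.seed, "extrude"),
                          extent_xy=(raster.shape[1] * raster.pixel_size,
                                     raster.shape[0] * raster.pixel_size),
                          axial_margin=plan.sin_amplitude,
                          sin_amplitude=plan.sin_amplitude,
                          side_segment=15.0)
    return assemble_lattice(block, rotation_rate=plan.rotation_rate)


def simulate_tensors(lattice: SubstrateLattice, kind: str, g_max: int,
                     d_ic: float, d_ec: float, n_particles: int, seed: int,
                     compartments: tuple[str, ...] = ("all",),
                     ) -> dict[str, DiffusionTensor]:
    """One realisation: walk the six directions, fit requested tensors."""
    spec = seqs.table1_spec(kind, g_max)
    cfg = RunConfig(d_ic=d_ic, d_ec=d_ec, n_particles=n_particles, seed=seed)
    waves = []
    bmats = []
    for d in seqs.direction_set():
        w = seqs.build_waveform(spec.with_direction(d), allow_residual=True)
        _, bm = seqs.bvalue(w)
        waves.append(seqs.discretize(w))
        bmats.append(bm)
    ens = seed_particles(lattice, cfg, waves[0].total_time)
    results = [run(lattice, w, cfg, ensemble=ens) for w in waves]
    out = {}
    for which in compartments:
        atts = []
        n_used = 0
        for res in results:
            mask = compartment_filter(res, which)
            n_used = int(mask.sum())
            a, _ = attenuation(res.phase[mask])
            atts.append(a)
        out[which] = fit_tensor(
            SignalSet(np.array(atts), np.array(bmats), n_used))
    return out


def _linfit(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """OLS slope, intercept and R^2."""
    slope, intercept = np.polyfit(x, y, 1)
    pred = slope * x + intercept
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return float(slope), float(intercept), r2


_METRICS = ("lambda1", "lambda2", "lambda3", "md", "fa", "mode")


def _combo_rows(lattice, plan, family, ecv, kind, g_max, d_ic, d_ec):
    """Per-realisation metric rows plus the stats row for one combo."""
    sub_hash = _hash_array(lattice.block.triangles)
    rows = []
    tensors = []
    for r in range(plan.n_real):
        s = derive_seed(plan.seed, family, round(ecv, 4), kind, g_max,
                        d_ic, d_ec, r)
        t = simulate_tensors(lattice, kind, g_max, d_ic, d_ec,
                             plan.n_p, s)["all"]
        tensors.append(t)
        rows.append({
            "family": family, "ecv": ecv, "sequence": kind, "g_max": g_max,
            "d_ic": d_ic, "d_ec": d_ec, "realisation": r, "seed": s,
            "substrate_hash": sub_hash, **t.metrics(),
        })
    if len(tensors) >= 3:
        st = realisation_stats(tensors)
        stats_row = {
            "family": family, "ecv": ecv, "sequence": kind, "g_max": g_max,
            "d_ic": d_ic, "d_ec": d_ec, "substrate_hash": sub_hash,
            "n_realisations": plan.n_real,
        }
        for m in _METRICS:
            stats_row[f"{m}_median"] = st.scalars[m]["median"]
            stats_row[f"{m}_ci_low"] = st.scalars[m]["ci_low"]
            stats_row[f"{m}_ci_high"] = st.scalars[m]["ci_high"]
        stats_row.update(st.cones)
    else:
        stats_row = {
            "family": family, "ecv": ecv, "sequence": kind, "g_max": g_max,
            "d_ic": d_ic, "d_ec": d_ec, "substrate_hash": sub_hash,
            "n_realisations": plan.n_real,
        }
        for m in _METRICS:
            vals = [row[m] for row in rows]
            stats_row[f"{m}_median"] = float(np.median(vals))
            stats_row[f"{m}_ci_low"] = float(np.min(vals))
            stats_row[f"{m}_ci_high"] = float(np.max(vals))
    return rows, stats_row


def run_ecv_sweep(plan: ExperimentPlan) -> dict[str, pd.DataFrame]:
    """Diffusion tensor metrics versus extra-cellular volume fraction.

    Returns ``realisations`` (one row per run), ``summary`` (medians/CIs
    per combination) and ``fits`` (slope m, intercept and R^2 of the
    per-combination linear fits of lambda1 and MD against ECV in
    percent).
    """
    real_rows = []
    summary_rows = []
    for family in plan.families:
        for ecv in plan.ecv_targets:
            try:
                lattice = build_substrate(plan, family, float(ecv))
            except ValueError as exc:
                print(f"[ecv-sweep] skipping {family} at ECV {ecv}: {exc}")
                continue
            for kind in plan.sequences:
                for g in plan.g_max:
                    for d_ic, d_ec in plan.diffusivities:
                        rows, srow = _combo_rows(lattice, plan, family,
                                                 float(ecv), kind, g,
                                                 d_ic, d_ec)
                        real_rows += rows
                        summary_rows.append(srow)
    summary = pd.DataFrame(summary_rows)
    fit_rows = []
    for (family, kind, g, d_ic, d_ec), grp in summary.groupby(
            ["family", "sequence", "g_max", "d_ic", "d_ec"]):
        if len(grp) < 3:
            continue
        x = grp["ecv"].to_numpy() * 100.0  # percent
        for metric in ("md", "lambda1"):
            m, b, r2 = _linfit(x, grp[f"{metric}_median"].to_numpy())
            fit_rows.append({
                "family": family, "sequence": kind, "g_max": g,
                "d_ic": d_ic, "d_ec": d_ec, "metric": metric,
                "slope_per_percent": m, "intercept": b, "r_squared": r2,
                "n_points": len(grp),
            })
    return {
        "realisations": pd.DataFrame(real_rows),
        "summary": summary,
        "fits": pd.DataFrame(fit_rows),
    }


def run_diffusivity_sweep(plan: ExperimentPlan,
                          ecv: float = 0.25,
                          d_ic_values: tuple[float, ...] | None = None,
                          d_ec_values: tuple[float, ...] = (2.0, 3.0),
                          family: str = "thickened"
                          ) -> dict[str, pd.DataFrame]:
    """MD and FA sensitivity to the compartment diffusivities.

    On a fixed substrate (default: histology-based at ECV 25 %), the
    intra-cellular diffusivity runs in 0.5 um^2/ms steps from 1.0 up to
    each extra-cellular value.
    """
    lattice = build_substrate(plan, family, ecv)
    real_rows = []
    summary_rows = []
    for d_ec in d_ec_values:
        dics = (d_ic_values if d_ic_values is not None
                else tuple(np.arange(1.0, d_ec + 1e-9, 0.5)))
        for d_ic in dics:
            for kind in plan.sequences:
                for g in plan.g_max:
                    rows, srow = _combo_rows(lattice, plan, family, ecv,
                                             kind, g, float(d_ic),
                                             float(d_ec))
                    real_rows += rows
                    summary_rows.append(srow)
    summary = pd.DataFrame(summary_rows)
    fit_rows = []
    for (kind, g, d_ec), grp in summary.groupby(["sequence", "g_max", "d_ec"]):
        if len(grp) < 2:
            continue
        x = grp["d_ic"].to_numpy()
        m, b, r2 = _linfit(x, grp["md_median"].to_numpy())
        fit_rows.append({
            "sequence": kind, "g_max": g, "d_ec": d_ec,
            "slope_md_per_dic": m, "intercept": b, "r_squared": r2,
            "md_monotonic": bool(np.all(np.diff(
                grp.sort_values("d_ic")["md_median"].to_numpy()) > 0)),
            "fa_monotonic": bool(np.all(np.diff(
                grp.sort_values("d_ic")["fa_median"].to_numpy()) > 0)),
        })
    return {
        "realisations": pd.DataFrame(real_rows),
        "summary": summary,
        "fits": pd.DataFrame(fit_rows),
    }


def run_gmax_comparison(plan: ExperimentPlan,
                        ecv: float = 0.25,
                        family: str = "cuboid") -> pd.DataFrame:
    """Delta-table: metric differences between 80 and 40 mT/m variants.

    Positive ``delta_md`` means the 80 mT/m variant of the sequence
    observes a higher MD than the 40 mT/m variant on the same substrate.
    """
    lattice = build_substrate(plan, family, ecv)
    rows = []
    for kind in plan.sequences:
        for d_ic, d_ec in plan.diffusivities:
            stats = {}
            for g in (40, 80):
                _, srow = _combo_rows(lattice, plan, family, ecv, kind, g,
                                      d_ic, d_ec)
                stats[g] = srow
            ci_w = max(stats[40]["md_ci_high"] - stats[40]["md_ci_low"],
                       stats[80]["md_ci_high"] - stats[80]["md_ci_low"])
            ci_w_fa = max(stats[40]["fa_ci_high"] - stats[40]["fa_ci_low"],
                          stats[80]["fa_ci_high"] - stats[80]["fa_ci_low"])
            rows.append({
                "family": family, "ecv": ecv, "sequence": kind,
                "d_ic": d_ic, "d_ec": d_ec,
                "md_40": stats[40]["md_median"], "md_80": stats[80]["md_median"],
                "fa_40": stats[40]["fa_median"], "fa_80": stats[80]["fa_median"],
                "delta_md": stats[80]["md_median"] - stats[40]["md_median"],
                "delta_fa": stats[80]["fa_median"] - stats[40]["fa_median"],
                "md_ci_width": ci_w, "fa_ci_width": ci_w_fa,
            })
    return pd.DataFrame(rows)
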