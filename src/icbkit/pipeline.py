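"""End-to-end synthetic study: generation and staged analysis.

``make_synthetic_study`` writes a complete eight-cell study (lesion x
treatment) to disk — trajectories for the three arenas, behavioural
state logs, gambling-task trials, and striatal sections — together
with its manifest.  ``run_pipeline`` consumes a manifest and emits one
results directory per figure analogue:

    fig2_openfield/  per-animal motion metrics + treatment ANOVA
    fig3_epm/        entries, distances + ANOVA
    fig4_states/     state totals, bout durations, switch rate
    fig5_checking/   the five checking parameters + ANOVA
    fig6_rigt/       per-animal block curves + group means
    fig7_ps6/        densities, lesion extent, difference/stat maps
    fig8_pca/        component maps, coefficients, expression ANOVA

All randomness flows from the single manifest seed through
``numpy.random.SeedSequence.spawn``, and every table is written with a
fixed float format, so a rerun with the same seed is byte-identical.

The synthetic group presets are illustrative regimes chosen to mirror
the direction of drug effects (hyperlocomotive, short-bout, strongly
checking D2/3-agonist-like groups versus baseline-like vehicle and
L-DOPA groups); they are not fits to any animal's data.
"""

from __future__ import annotations

from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as _io
from . import pca as _pca
from . import rigt as _rigt
from . import spatial as _sp
from . import states as _states
from . import stats as _st
from . import trajectory as _tm
from .arenas import checking_platform, epm, open_field
from .checking import analyze_checking, build_zone_grid
from .manifest import StudyManifest, TREATMENTS, validate_manifest
from .synthetic import (
    AgentParams,
    SectionGenParams,
    StateLogParams,
    TrajectoryParams,
    default_lesion_polygon,
    gen_choices,
    gen_sections,
    gen_state_log,
    gen_trajectory,
)

STAGES = ("openfield", "epm", "states", "checking", "rigt", "sections", "pca")

# candidate home-base zones: the four interior grid positions where the
# plexiglass boxes sit (row-major ids on the 5 x 5 grid)
BOX_ZONES = (6, 8, 16, 18)

HYPERLOCOMOTIVE = ("R2.5", "LD24+R2.5")

# illustrative per-treatment behavioural regimes (not fits): the D2/3
# agonist arms are hyperlocomotive, strongly home-base attracted, short
# of bout, and learn the gambling task poorly
_WALK = {
    "saline": dict(mobility_fraction=0.35, mean_speed=10.0, attraction_strength=2.0,
                   visit_dwell_mean=4.0),
    "LD24": dict(mobility_fraction=0.30, mean_speed=9.0, attraction_strength=2.0,
                 visit_dwell_mean=5.0),
    "R2.5": dict(mobility_fraction=0.85, mean_speed=25.0, attraction_strength=6.0,
                 visit_dwell_mean=1.2),
    "LD24+R2.5": dict(mobility_fraction=0.75, mean_speed=20.0,
                      attraction_strength=5.5, visit_dwell_mean=1.4),
}

_BOUTS = {
    "saline": dict(locomoting=6.0, rearing=5.0, grooming=8.0,
                   **{"sniffing up": 5.0, "sniffing down": 6.0}),
    "LD24": dict(locomoting=6.0, rearing=6.0, grooming=10.0,
                 **{"sniffing up": 6.0, "sniffing down": 7.0}),
    "R2.5": dict(locomoting=3.0, rearing=2.0, grooming=2.0,
                 **{"sniffing up": 2.0, "sniffing down": 2.5}),
    "LD24+R2.5": dict(locomoting=3.0, rearing=2.5, grooming=2.0,
                      **{"sniffing up": 2.0, "sniffing down": 3.0}),
}

_AGENT = {
    "saline": dict(learning_rate=0.25, inverse_temperature=4.0),
    "LD24": dict(learning_rate=0.20, inverse_temperature=3.0),
    "R2.5": dict(learning_rate=0.05, inverse_temperature=0.6),
    "LD24+R2.5": dict(learning_rate=0.05, inverse_temperature=0.8),
}

_SECTIONS = {
    "saline": dict(base_intensity=120.0,
                   pattern_weights={"dorsolateral_gradient": 1.2}),
    "LD24": dict(base_intensity=140.0,
                 pattern_weights={"dorsolateral_gradient": 1.3}),
    "R2.5": dict(base_intensity=50.0,
                 pattern_weights={"dorsolateral_gradient": -0.4,
                                  "centromedial_shift": 1.2}),
    "LD24+R2.5": dict(base_intensity=80.0,
                      pattern_weights={"dorsolateral_gradient": -0.2,
                                       "centromedial_shift": 1.0}),
}
_LESION_HOTSPOT_WEIGHT = 0.8


def _seed_registry(master: int) -> dict:
    """Named child seeds spawned from one master seed."""
    ss = np.random.SeedSequence(master)
    names = ("walk", "states", "agent", "sections", "misc")
    children = ss.spawn(len(names))
    return {n: int(c.generate_state(1)[0] % (2**31)) for n, c in zip(names, children)}


def make_synthetic_study(
    outdir,
    seed: int = 0,
    n_per_group: int = 3,
    of_minutes: float = 10.0,
    cc_minutes: float = 45.0,
    epm_minutes: float = 5.0,
    sample_rate: float = 5.0,
) -> Path:
    """Generate a complete synthetic study; returns the manifest path."""
    outdir = Path(outdir)
    for sub in ("of", "cc", "epm", "states", "rigt", "sections"):
        (outdir / sub).mkdir(parents=True, exist_ok=True)
    seeds = _seed_registry(seed)
    entries = []
    all_sections = []
    idx = 0
    for lesion in ("sham", "6-OHDA"):
        for treatment in TREATMENTS:
            for k in range(n_per_group):
                aid = f"{lesion.replace('-', '')}_{treatment.replace('+', '')}_{k:02d}"
                aid = aid.replace(".", "")
                base = seeds["walk"] + 1000 * idx
                walk = _WALK[treatment]
                entry = {"id": aid, "lesion": lesion, "treatment": treatment}

                # open field
                traj = gen_trajectory(TrajectoryParams(
                    duration=of_minutes * 60, sample_rate=sample_rate,
                    arena=open_field(), seed=base + 1, **walk))
                _io.write_trajectory_csv(traj, outdir / "of" / f"{aid}.csv")
                entry["open_field"] = f"of/{aid}.csv"

                # checking platform with one box zone as planted home base
                rng = np.random.default_rng(base + 2)
                home = int(rng.choice(BOX_ZONES))
                traj = gen_trajectory(TrajectoryParams(
                    duration=cc_minutes * 60, sample_rate=sample_rate,
                    arena=checking_platform(), home_base_zones=(home,),
                    seed=base + 2, **walk))
                traj.meta["home_zone"] = home
                _io.write_trajectory_csv(traj, outdir / "cc" / f"{aid}.csv")
                entry["checking"] = f"cc/{aid}.csv"

                # elevated plus maze
                traj = gen_trajectory(TrajectoryParams(
                    duration=epm_minutes * 60, sample_rate=sample_rate,
                    arena=epm(), seed=base + 3, **walk))
                _io.write_trajectory_csv(traj, outdir / "epm" / f"{aid}.csv")
                entry["epm"] = f"epm/{aid}.csv"

                # behavioural states
                bouts = _BOUTS[treatment]
                logs = gen_state_log(StateLogParams(
                    states=tuple(bouts), bout_mean=dict(bouts),
                    n_windows=3, seed=seeds["states"] + idx))
                _io.write_event_log_csv(logs, outdir / "states" / f"{aid}.csv",
                                        seed=seeds["states"] + idx)
                entry["states"] = f"states/{aid}.csv"

                # gambling task: lesioned cohort only, as in the protocol
                if lesion == "6-OHDA":
                    recs = gen_choices(AgentParams(
                        animal=aid, seed=seeds["agent"] + idx, **_AGENT[treatment]))
                    _io.write_trials_csv(recs, outdir / "rigt" / f"{aid}.csv",
                                         seed=seeds["agent"] + idx)
                    entry["trials"] = f"rigt/{aid}.csv"

                # striatal sections
                sect_kwargs = dict(_SECTIONS[treatment])
                weights = dict(sect_kwargs.pop("pattern_weights"))
                lesion_poly = None
                if lesion == "6-OHDA":
                    weights["lesion_hotspot"] = _LESION_HOTSPOT_WEIGHT
                    lesion_poly = default_lesion_polygon()
                secs = gen_sections(SectionGenParams(
                    pattern_weights=weights, lesion_polygon=lesion_poly,
                    n_animals=1, group=f"{lesion}:{treatment}",
                    seed=seeds["sections"] + idx, **sect_kwargs))
                for s in secs:
                    s.animal = aid
                    s.meta["lesion"] = lesion
                    s.meta["treatment"] = treatment
                all_sections.extend(secs)

                entries.append(entry)
                idx += 1

    _io.write_sections(all_sections, outdir / "sections" / "cells.csv",
                       outdir / "sections" / "outlines.json", seed=seeds["sections"])
    manifest = {
        "seed": seed,
        "animals": entries,
        "sections": {"cells": "sections/cells.csv",
                     "outlines": "sections/outlines.json"},
    }
    mpath = outdir / "manifest.yaml"
    mpath.write_text(yaml.safe_dump(manifest, sort_keys=True))
    return mpath


# ---------------------------------------------------------------------------
# analysis stages
# ---------------------------------------------------------------------------


def _anova_table(df: pd.DataFrame, value: str) -> pd.DataFrame:
    res = _st.two_factor_anova(df[value], df["treatment"], df["lesion"])
    rows = [
        {"effect": k, "F": r.statistic, "df1": r.df[0], "df2": r.df[-1],
         "p": r.pvalue}
        for k, r in res.items() if k != "residual"
    ]
    return pd.DataFrame(rows)


def _stage_openfield(manifest: StudyManifest, out: Path) -> None:
    rows = []
    for a in manifest.animals:
        if "open_field" not in a.files:
            continue
        traj = _io.read_trajectory_csv(a.files["open_field"])
        s = _tm.summarize_open_field(traj)
        rows.append({"animal": a.id, "lesion": a.lesion, "treatment": a.treatment,
                     "total_distance_m": s.total_distance_m,
                     "time_mobile_s": s.time_mobile_s,
                     "max_speed_ms": s.max_speed_ms,
                     "inner_zone_fraction": s.inner_zone_fraction})
    df = pd.DataFrame(rows)
    _io.write_table(df, out / "metrics.csv")
    for metric in ("total_distance_m", "time_mobile_s", "max_speed_ms",
                   "inner_zone_fraction"):
        _io.write_table(_anova_table(df, metric), out / f"anova_{metric}.csv")


def _stage_epm(manifest: StudyManifest, out: Path) -> None:
    rows = []
    for a in manifest.animals:
        if "epm" not in a.files:
            continue
        traj = _io.read_trajectory_csv(a.files["epm"])
        s = _tm.summarize_epm(traj)
        rows.append({"animal": a.id, "lesion": a.lesion, "treatment": a.treatment,
                     "open_arm_entry_fraction": s.open_arm_entry_fraction,
                     "total_distance_m": s.total_distance_m})
    df = pd.DataFrame(rows)
    _io.write_table(df, out / "metrics.csv")
    scored = df.dropna(subset=["open_arm_entry_fraction"])
    if scored["treatment"].nunique() > 1 and scored["lesion"].nunique() > 1:
        _io.write_table(_anova_table(scored, "open_arm_entry_fraction"),
                        out / "anova_open_arm_entry_fraction.csv")


def _stage_states(manifest: StudyManifest, out: Path) -> None:
    rows = []
    for a in manifest.animals:
        if "states" not in a.files:
            continue
        logs = _io.read_event_log_csv(a.files["states"])
        summ = _states.summarize_states(logs)
        row = {"animal": a.id, "lesion": a.lesion, "treatment": a.treatment,
               "switch_rate": summ.switch_rate}
        for st, v in summ.total_time.items():
            row[f"total_{st.replace(' ', '_')}"] = v
        for st, v in summ.bout_duration.items():
            row[f"bout_{st.replace(' ', '_')}"] = v
        rows.append(row)
    _io.write_table(pd.DataFrame(rows), out / "metrics.csv")


def _stage_checking(manifest: StudyManifest, out: Path) -> None:
    grid = build_zone_grid()
    rows = []
    for a in manifest.animals:
        if "checking" not in a.files:
            continue
        traj = _io.read_trajectory_csv(a.files["checking"])
        cls = "hyperlocomotive" if a.treatment in HYPERLOCOMOTIVE else "baseline_like"
        rep = analyze_checking(traj, cls, grid)
        rows.append({"animal": a.id, "lesion": a.lesion, "treatment": a.treatment,
                     "window_class": cls,
                     "home_bases": ";".join(map(str, rep.home_bases)),
                     "frequency": rep.frequency,
                     "ratio_obs_exp": rep.ratio_obs_exp,
                     "mean_visit_time": rep.mean_visit_time,
                     "mean_return_time": rep.mean_return_time,
                     "stops_between_checks": rep.stops_between_checks})
    df = pd.DataFrame(rows)
    _io.write_table(df, out / "metrics.csv")
    complete = df.dropna(subset=["ratio_obs_exp"])
    if len(complete) > 8:
        _io.write_table(_anova_table(complete, "ratio_obs_exp"),
                        out / "anova_ratio_obs_exp.csv")


def _stage_rigt(manifest: StudyManifest, out: Path) -> None:
    per_animal = {}
    labels = {}
    for a in manifest.animals:
        if "trials" not in a.files:
            continue
        recs = _io.read_trials_csv(a.files["trials"])
        recs, audit = _rigt.apply_exclusions(recs)
        if not recs:
            continue
        per_animal[a.id] = recs
        labels[a.id] = a.treatment
    if not per_animal:
        return
    curves = _rigt.group_curves(per_animal)
    curves["treatment"] = curves["animal"].map(labels)
    _io.write_table(curves, out / "curves.csv")
    means = curves.groupby(["treatment", "block"], as_index=False)[
        ["empty_fraction", "advantageous_fraction"]].mean()
    _io.write_table(means, out / "group_means.csv")
    chance = _rigt.chance_levels(_rigt.RewardSchedule.standard())
    _io.write_table(pd.DataFrame([{"empty_chance": chance[0],
                                   "advantageous_chance": chance[1]}]),
                    out / "chance_levels.csv")


def _load_sections(manifest: StudyManifest):
    secs = _io.read_sections(manifest.sections["cells"],
                             manifest.sections["outlines"])
    lab = {a.id: (a.lesion, a.treatment) for a in manifest.animals}
    for s in secs:
        if s.animal in lab:
            s.meta["lesion"], s.meta["treatment"] = lab[s.animal]
    return secs


def _stage_sections(manifest: StudyManifest, out: Path, refine: bool):
    sections = _load_sections(manifest)
    dens = _sp.density_per_animal(sections, "total")
    _io.write_table(dens, out / "density_total.csv")
    extent = pd.DataFrame(
        [{"animal": s.animal, "group": s.group, "level": s.level,
          "hemisphere": s.hemisphere, "pct_intact": _sp.lesion_extent(s)}
         for s in sections])
    _io.write_table(extent, out / "lesion_extent.csv")
    maps, reference, grid = _sp.build_maps(sections, refine=refine)
    mask = _sp.striatum_mask(reference, grid)
    np.savetxt(out / "striatum_mask.csv", mask.astype(int), fmt="%d", delimiter=",")
    _io.write_matrix_csv(reference, out / "reference_outline_um.csv")

    groups: dict[str, list] = {}
    for m in maps:
        key = f"{m.meta.get('lesion', '')}:{m.meta.get('treatment', '')}"
        groups.setdefault(key, []).append(m)
    for key, ms in sorted(groups.items()):
        mean_map = np.mean([m.counts for m in ms], axis=0)
        _io.write_matrix_csv(mean_map, out / f"mean_map_{key.replace(':', '_')}.csv")
    # difference and statistical map for the headline contrast
    a_key = next((k for k in sorted(groups) if k.endswith(":R2.5")), None)
    b_key = next((k for k in sorted(groups) if k.endswith(":saline")), None)
    if a_key and b_key and len(groups[a_key]) >= 3 and len(groups[b_key]) >= 3:
        diff = _sp.group_difference_map(groups[a_key], groups[b_key], mask)
        _io.write_matrix_csv(np.nan_to_num(diff), out / "diff_R25_vs_saline.csv")
        stat = _sp.pixelwise_test(groups[a_key], groups[b_key], mask, alpha=0.01)
        np.savetxt(out / "sig_R25_vs_saline.csv", stat.significant.astype(int),
                   fmt="%d", delimiter=",")
    return maps, mask


def _stage_pca(maps, mask, out: Path) -> None:
    matrix = _pca.build_matrix(maps)
    model = _pca.sign_align(_pca.fit_pca(matrix))
    for k in range(min(3, model.n_components)):
        _io.write_matrix_csv(_pca.unflatten(model.components[k], model.grid),
                             out / f"pc{k + 1}_map.csv")
    evr = pd.DataFrame({"component": np.arange(1, model.n_components + 1),
                        "explained_variance_ratio": model.explained_variance_ratio})
    _io.write_table(evr.head(10), out / "explained_variance.csv")
    coef = _pca.coefficient_table(model, 3)
    _io.write_table(coef, out / "coefficients.csv")
    if {"lesion", "treatment"} <= set(coef.columns):
        expr = _pca.pattern_expression(model, 3)
        _io.write_table(expr["per_animal"], out / "per_animal_coefficients.csv")


def run_pipeline(manifest_path, results_dir, stages=None, refine_alignment=False):
    """Run the staged analysis for a manifest; returns the results dir.

    ``stages`` is an ordered subset of :data:`STAGES`; section mapping
    always precedes PCA (the dependency is enforced here).
    """
    manifest = validate_manifest(manifest_path, parse_files=False)
    stages = list(stages) if stages else list(STAGES)
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    if "pca" in stages and "sections" not in stages:
        stages.insert(stages.index("pca"), "sections")
    results = Path(results_dir)
    dirs = {
        "openfield": "fig2_openfield", "epm": "fig3_epm", "states": "fig4_states",
        "checking": "fig5_checking", "rigt": "fig6_rigt",
        "sections": "fig7_ps6", "pca": "fig8_pca",
    }
    maps = mask = None
    for stage in STAGES:  # fixed dependency order
        if stage not in stages:
            continue
        out = results / dirs[stage]
        out.mkdir(parents=True, exist_ok=True)
        if stage == "openfield":
            _stage_openfield(manifest, out)
        elif stage == "epm":
            _stage_epm(manifest, out)
        elif stage == "states":
            _stage_states(manifest, out)
        elif stage == "checking":
            _stage_checking(manifest, out)
        elif stage == "rigt":
            _stage_rigt(manifest, out)
        elif stage == "sections":
            if not manifest.sections:
                continue
            maps, mask = _stage_sections(manifest, out, refine_alignment)
        elif stage == "pca":
            if maps is None:
                continue
            _stage_pca(maps, mask, out)
    return results
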