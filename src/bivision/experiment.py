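"""Experiment driver: simulate -> model -> evaluate, streaming frames.

``run_scenario`` renders one scenario and pushes every frame through any
number of model variants simultaneously (plus the spatial local-contrast
baseline with and without motion inhibition), so the renderer runs once per
scenario regardless of how many methods are compared.  Warm-up frames update
model state only; evaluation frames are scored.  Everything is deterministic
given the scenario config and seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import comparators
from .evaluation import auroc, match, mcpp, mfm, roc, winner_take_all
from .inhibition import InhibitionConfig, condition, to_suppression
from .pipeline import BIVModel, MotionBranch
from .scene import ScenarioConfig, make_scene

#: matching-window shift for methods that respond on the trailing edge of
#: right-to-left motion (the temporally correlating models); spatial-only
#: methods use no shift
TRAILING_EDGE_SHIFT = (0, 1)
NO_SHIFT = (0, 0)


@dataclass
class MethodResult:
    name: str
    auroc: float
    tp_at_fp_max: float
    curve: object


def tp_at(curve, fp=20.0):
    """Per-frame mean true positives at a given false-positive level."""
    if len(curve.fp) == 0:
        return 0.0
    return float(np.interp(fp, curve.fp, curve.tp))


def run_scenario(cfg: ScenarioConfig, seed, variants=("biv08",),
                 include_lcm=False, clutter_gain=1.0, fp_max=20.0,
                 wta_kernel=7, match_window=5, collect_maps=False):
    """Score model variants on one synthetic scenario.

    Returns ``(results, metrics)`` where ``results`` maps method name to a
    :class:`MethodResult` and ``metrics`` holds the scenario clutter metrics
    (computed on the first evaluation frame, background only applies).  When
    ``include_lcm`` is true the local-contrast baseline is scored with and
    without motion inhibition; its suppression comes from a statically
    conditioned motion branch at the published pooling corner.
    """
    renderer = make_scene(cfg, panorama_seed=seed, clutter_gain=clutter_gain)
    models = {name: BIVModel.from_variant(name) for name in variants}
    labelled = {name: [] for name in variants}
    lcm_branch = None
    static_cfg = None
    if include_lcm:
        # suppression for the external comparator: statically conditioned
        # motion tap, pooled over a window matching the 9x9 footprint of the
        # 3x3-cell contrast kernel so the suppression covers every site the
        # comparator responds at
        from .motion import PoolingConfig
        lcm_branch = MotionBranch(pooling=PoolingConfig(spatial_size=9))
        static_cfg = InhibitionConfig()
        labelled["lcm"] = []
        labelled["lcm-inhib"] = []
    metrics = {}
    maps = {name: [] for name in labelled} if collect_maps else None
    width = cfg.decimated_shape[1]
    for i, (frame, truth) in enumerate(renderer.frames()):
        step_results = {name: model.step(frame)
                        for name, model in models.items()}
        suppression = None
        if include_lcm:
            tap, _ = lcm_branch.step(frame)
            suppression = to_suppression(condition(tap, static_cfg))
        if i < cfg.warmup_frames:
            continue
        if not metrics:
            metrics = {"mcpp": mcpp(frame), "mfm": mfm(frame)}
        for name, res in step_results.items():
            dets = winner_take_all(res.dark, kernel=wta_kernel)
            labelled[name].extend(match(dets, truth, frame=i,
                                        window=match_window,
                                        shift_px=TRAILING_EDGE_SHIFT,
                                        frame_width=width))
            if collect_maps:
                maps[name].append(res.dark)
        if include_lcm:
            contrast = comparators.lcm(frame)
            inhibited = comparators.inhibit_external(contrast, suppression)
            for name, sal in (("lcm", contrast), ("lcm-inhib", inhibited)):
                dets = winner_take_all(sal, kernel=wta_kernel, polarity="min")
                labelled[name].extend(match(dets, truth, frame=i,
                                            window=match_window,
                                            shift_px=NO_SHIFT,
                                            frame_width=width))
                if collect_maps:
                    maps[name].append(sal)
    results = {}
    for name, dets in labelled.items():
        curve = roc(dets, n_frames=cfg.eval_frames,
                    targets_per_frame=cfg.n_targets)
        results[name] = MethodResult(name=name, auroc=auroc(curve, fp_max),
                                     tp_at_fp_max=tp_at(curve, fp_max),
                                     curve=curve)
    if collect_maps:
        return results, metrics, maps
    return results, metrics


@dataclass
class ExperimentSpec:
    """A grid of scenarios: seeds x speed pairs x clutter gains, each scored
    for every requested method."""

    scenario: ScenarioConfig = field(default_factory=ScenarioConfig)
    variants: tuple = ("biv08", "biv19", "biv22-static", "biv22-mli")
    seeds: tuple = (1, 2, 3, 4, 5)
    speeds: tuple = ((17.0, 17.0), (29.0, 29.0))   # (target, background) px/s
    clutter_gains: tuple = (1.0,)
    include_lcm: bool = False
    fp_max: float = 20.0


def run_experiment(spec: ExperimentSpec, progress=None):
    """Run the grid and return a tidy result table.

    One row per (method, seed, speed pair, clutter gain) with the AUROC (to
    ``fp_max`` false positives), the per-frame true positives at that level
    and the scenario clutter metrics.
    """
    from dataclasses import replace

    rows = []
    for clutter in spec.clutter_gains:
        for target_speed, background_speed in spec.speeds:
            cfg = replace(spec.scenario, target_speed=target_speed,
                          background_speed=background_speed)
            for seed in spec.seeds:
                results, metrics = run_scenario(
                    cfg, seed, variants=spec.variants,
                    include_lcm=spec.include_lcm, clutter_gain=clutter,
                    fp_max=spec.fp_max)
                for name, res in results.items():
                    rows.append(dict(method=name, seed=seed,
                                     target_speed=target_speed,
                                     background_speed=background_speed,
                                     clutter_gain=clutter,
                                     auroc=res.auroc,
                                     tp_at_fp_max=res.tp_at_fp_max,
                                     **metrics))
                if progress is not None:
                    progress(clutter, (target_speed, background_speed), seed)
    return pd.DataFrame(rows)


def median_by_method(table):
    """Median AUROC per method over all scenarios in the table."""
    return table.groupby("method")["auroc"].median()


def spec_from_yaml(path):
    """Load an :class:`ExperimentSpec` from a YAML file.

    Top-level keys mirror the dataclass fields; ``scenario`` is a mapping
    of :class:`~bivision.scene.ScenarioConfig` fields.
    """
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    scenario = ScenarioConfig(**{
        k: tuple(v) if k == "decimated_shape" else v
        for k, v in (raw.pop("scenario", {}) or {}).items()})
    for key in ("variants", "seeds", "clutter_gains"):
        if key in raw:
            raw[key] = tuple(raw[key])
    if "speeds" in raw:
        raw["speeds"] = tuple(tuple(pair) for pair in raw["speeds"])
    return ExperimentSpec(scenario=scenario, **raw)
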