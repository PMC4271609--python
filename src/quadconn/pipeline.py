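"""End-to-end pipeline: phantom -> four measures -> six-pair comparison.

Fully deterministic under the config seed: the global seed is fanned out to
per-stage child generators via ``numpy.random.SeedSequence`` spawning, so a
repeated run writes byte-identical comparison outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as qio
from . import crossmodal
from .errors import ConfigError
from .phantom import PhantomConfig, build_phantom
from .workflow import (
    MeasureParams,
    contact_targets,
    measure_all,
    measure_desfmri,
    measure_rsfmri,
    measure_structural,
)

log = logging.getLogger("quadconn")


@dataclass(frozen=True)
class PipelineConfig:
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    params: MeasureParams = field(default_factory=MeasureParams)

    @classmethod
    def from_dict(cls, obj: dict) -> "PipelineConfig":
        ph = PhantomConfig(**{k: _detuple(v) for k, v in obj.get("phantom", {}).items()})
        p = obj.get("params", {})
        window = p.pop("window", None)
        mp = MeasureParams(**p) if window is None else MeasureParams(
            window=_window_from_tag(window), **p
        )
        return cls(ph, mp)

    def to_dict(self) -> dict:
        d = {"phantom": dataclasses.asdict(self.phantom),
             "params": dataclasses.asdict(self.params)}
        d["params"]["window"] = d["params"]["window"]["purpose"]
        return d


def _detuple(v):
    return tuple(v) if isinstance(v, list) else v


def _window_from_tag(tag: str):
    from .ccep import FUNCTIONAL_WINDOW, STRUCTURAL_WINDOW

    if tag == "functional":
        return FUNCTIONAL_WINDOW
    if tag == "structural":
        return STRUCTURAL_WINDOW
    raise ConfigError(f"unknown window tag {tag!r}")


def run_full_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run phantom generation, all four measures and all six comparisons.

    Writes phantom artifacts, per-modality maps/value tables, and the
    comparison matrix (TSV + JSON) under ``outdir``.  Returns a summary dict
    with the comparison matrix and file paths.  Any stage failure aborts with
    a stage-tagged message; artifacts already written are retained.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    qio.write_config(config.to_dict(), out / "config.yaml")

    timings: dict[str, float] = {}

    def stage(name):
        class _Timer:
            def __enter__(self):
                self.t0 = time.perf_counter()
                log.info("stage %s: start", name)
                return self

            def __exit__(self, exc_type, exc, tb):
                timings[name] = time.perf_counter() - self.t0
                if exc is not None:
                    log.error("stage %s: FAILED after %.1fs", name, timings[name])
                    raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
                log.info("stage %s: done in %.2fs", name, timings[name])

        return _Timer()

    with stage("phantom"):
        ph = build_phantom(config.phantom)
        qio.write_nifti(ph.masks.gm.astype(float), ph.grid, out / "gm_mask.nii.gz")
        qio.write_nifti(ph.masks.csf.astype(float), ph.grid, out / "csf_mask.nii.gz")
        qio.write_nifti(ph.masks.wm.astype(float), ph.grid, out / "wm_mask.nii.gz")
        qio.write_nifti(ph.rest_bold.data, ph.grid, out / "rest_bold.nii.gz",
                        tr_s=ph.config.tr_s)
        qio.write_nifti(ph.des_bold.data, ph.grid, out / "des_bold.nii.gz",
                        tr_s=ph.config.tr_s)
        qio.write_fod(ph.fod, out / "fod.nii.gz")
        qio.write_electrodes(ph.electrodes, out / "electrodes.tsv")
        onsets = np.arange(ph.config.n_trials, dtype=float)  # 1 Hz pulses
        qio.write_events(onsets, np.where(np.arange(ph.config.n_trials) % 2 == 0, 1, -1),
                         out / "events.tsv")
        (out / "network.json").write_text(ph.network.to_json())

    params = config.params
    with stage("measures"):
        rs_map, _ = measure_rsfmri(ph, params)
        des_map, _ = measure_desfmri(ph, params)
        dmri_map, _ = measure_structural(ph, params)
        values = measure_all(ph, params)
        qio.write_nifti(np.nan_to_num(rs_map), ph.grid, out / "rsfmri_corr.nii.gz")
        qio.write_nifti(np.nan_to_num(des_map), ph.grid, out / "desfmri_t.nii.gz")
        qio.write_nifti(np.nan_to_num(dmri_map), ph.grid, out / "dmri_score.nii.gz")
        for name, vals in values.items():
            qio.write_value_table(vals, out / f"values_{name}.tsv")

    with stage("compare"):
        targets = contact_targets(ph, params)
        matrix = crossmodal.comparison_matrix(values, targets)
        matrix.to_csv(out / "comparison_matrix.tsv", sep="\t", index=False,
                      float_format="%.10g")
        payload = {
            f"{r.modality_a}__{r.modality_b}": {"r2": r.r2, "p": r.p, "n": int(r.n)}
            for r in matrix.itertuples()
        }
        (out / "comparison_matrix.json").write_text(
            json.dumps(payload, indent=1, sort_keys=True)
        )

    log.info("timings: %s", {k: round(v, 2) for k, v in timings.items()})
    return {"matrix": matrix, "outdir": str(out), "timings": timings}
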