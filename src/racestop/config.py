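"""YAML configuration loader for cohort simulation."""

from __future__ import annotations

from pathlib import Path

import yaml

from .race_sim import CohortSpec, GroupCovariates, RaceParams, RoiEffect
from .task_design import DesignSpec


def load_cohort_spec(path: str | Path) -> CohortSpec:
    """Build a :class:`CohortSpec` from a YAML file whose keys mirror the
    dataclass fields; nested blocks (base_params, design, *_covariates,
    roi_effects) map to their dataclasses. Missing keys keep defaults."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    kw = dict(raw)
    if "base_params" in kw:
        kw["base_params"] = RaceParams(**kw["base_params"])
    if "design" in kw:
        kw["design"] = DesignSpec(**kw["design"])
    for key in ("rpg_covariates", "iag_covariates"):
        if key in kw:
            kw[key] = GroupCovariates(
                **{
                    k: tuple(v) if isinstance(v, list) else v
                    for k, v in kw[key].items()
                }
            )
    if "roi_effects" in kw:
        kw["roi_effects"] = {
            name: RoiEffect(
                cell_means={
                    tuple(k.split("/")): v
                    for k, v in eff.get("cell_means", {}).items()
                },
                noise_sd=eff.get("noise_sd", 1.0),
                mets_rho=eff.get("mets_rho", 0.0),
            )
            for name, eff in kw["roi_effects"].items()
        }
    return CohortSpec(**kw)
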