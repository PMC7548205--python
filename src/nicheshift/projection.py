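"""Project a fitted model onto climate-scenario layer stacks.

Each scenario (an RCP forcing pathway at a time horizon) is realized by
several general circulation models (GCMs).  The model is evaluated on
every GCM's stack on the probability (cloglog/logistic) scale and the
per-cell unweighted mean across GCMs is the ensemble projection.
Non-climate layers (soil, elevation) are expected to be identical across
the member stacks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import maxent_engine as me
from .grid_io import AlignmentError, Grid, LayerStack


@dataclass
class ScenarioProjection:
    scenario_tag: str
    per_gcm: dict[str, Grid] = field(default_factory=dict)
    ensemble: Grid = None
    transform: str = "cloglog"
    clamp: bool = True

    @property
    def n_gcms(self) -> int:
        return len(self.per_gcm)


def project_current(
    model: me.MaxentModel,
    stack: LayerStack,
    transform: str = "cloglog",
    clamp: bool = True,
) -> Grid:
    """Single-stack convenience wrapper around :func:`maxent_engine.predict`."""
    return me.predict(model, stack, transform=transform, clamp=clamp)


def project_scenario(
    model: me.MaxentModel,
    stacks: dict[str, LayerStack] | list[LayerStack],
    transform: str = "cloglog",
    clamp: bool = True,
    scenario_tag: str | None = None,
) -> ScenarioProjection:
    """Predict per GCM and average cellwise into the ensemble grid.

    ``stacks`` maps GCM name to that GCM's layer stack (a plain list is
    accepted, keyed by each stack's scenario_tag).  The ensemble mean is
    nodata wherever any member is nodata.
    """
    if not isinstance(stacks, dict):
        stacks = {s.scenario_tag: s for s in stacks}
    if not stacks:
        raise ValueError("need at least one GCM stack")
    per_gcm: dict[str, Grid] = {}
    template = None
    for name, stack in stacks.items():
        g = me.predict(model, stack, transform=transform, clamp=clamp)
        g.name = f"{name}_{transform}"
        if template is None:
            template = g
        elif not g.same_geometry(template):
            raise AlignmentError(f"GCM {name!r} projection geometry mismatch")
        per_gcm[name] = g

    grids = list(per_gcm.values())
    mask = np.zeros(template.values.shape, dtype=bool)
    for g in grids:
        mask |= g.mask
    stackv = np.stack([g.values for g in grids])
    mean = stackv.mean(axis=0)
    mean[mask] = template.nodata
    tag = scenario_tag or template.name
    ensemble = template.with_values(mean, name=f"{tag}_ensemble")
    return ScenarioProjection(
        scenario_tag=tag, per_gcm=per_gcm, ensemble=ensemble,
        transform=transform, clamp=clamp,
    )
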