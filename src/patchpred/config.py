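"""Run configuration: every tunable of the pipeline with its shipped default.

The defaults are the settings of the shipped model: 14 A patches grown with a
120 deg solvent-angle threshold and 0.2 A contact tolerance, patch centres at
>25% relative accessibility, a 10% surface floor, and a 100-tree random forest
sampling 3 features per split.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass


@dataclass
class RunConfig:
    # solvent accessibility
    probe_radius: float = 1.4          # A, water probe
    point_density: int = 960           # sphere points per atom (Shrake-Rupley)
    radius_table_path: str | None = None
    rasa_reference_path: str | None = None

    # patch growth
    patch_radius: float = 14.0         # A (9 A is the alternative tested radius)
    solvent_angle_threshold: float = 120.0  # deg
    contact_tolerance: float = 0.2     # A added to the vdW-radius sum
    neighbour_count: int = 10          # residues in the geometry-vector centroid
    centre_rasa_threshold: float = 25.0  # % RASA, strict > for patch centres

    # labelling / surface definition
    interface_delta_rasa: float = 10.0  # percentage points, >= is interface
    surface_rasa_threshold: float = 10.0  # % RASA, >= counts as surface

    # learning
    n_trees: int = 100
    m_try: int = 3
    seed: int = 0

    # structure reading
    filter_peptides: bool = False      # drop chains < 30 residues when True
    min_chain_length: int = 30

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        return cls(**json.loads(text))

    def replace(self, **kw) -> "RunConfig":
        return dataclasses.replace(self, **kw)


DEFAULT_CONFIG = RunConfig()
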