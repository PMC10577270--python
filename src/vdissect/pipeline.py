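"""End-to-end virtual dissection pipeline.

``dissect`` chains the erosion-dilation core, anatomical classification
and perpendicular-plane boundary refinement into a single call returning a
:class:`DissectionResult`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .centerline import refine_boundaries
from .grid import AtriumLabelMap, StructuringElement, VoxelGrid
from .morphology import dissect_raw
from .parsing import (
    IterationPredictor,
    classify_structures,
    extract_features,
    rescue_missed_structures,
)


@dataclass
class DissectionConfig:
    """Tunable parameters of the dissection pipeline.

    tau_e : erosion-index threshold ending iterative erosion (solidity)
    gamma : minimal marginal dilation-index gain, as a fraction of shell volume
    n_max : erosion iteration cap
    min_structure_volume : mm^3 below which remnants are merged into the LA
    refine : apply centerline-perpendicular boundary refinement
    rescue : detect appendages protruding beyond the fitted LA ellipsoid
        that the erosion-dilation stage failed to separate
    """

    element: StructuringElement = StructuringElement.FACE6
    tau_e: float = 0.94
    gamma: float = 0.005
    n_max: int = 15
    min_structure_volume: float = 300.0
    refine: bool = True
    rescue: bool = True
    n_e: int | None = None
    n_d: int | None = None

    @classmethod
    def from_dict(cls, d: dict) -> "DissectionConfig":
        kwargs = {k: v for k, v in d.items() if k in cls.__dataclass_fields__}
        if isinstance(kwargs.get("element"), str):
            kwargs["element"] = StructuringElement[kwargs["element"].upper()]
        return cls(**kwargs)


@dataclass
class DissectionResult:
    """Final label map plus everything the pipeline produced on the way."""

    labelmap: AtriumLabelMap
    raw_labelmap: AtriumLabelMap  # classified, before boundary refinement
    traces: dict
    cut_planes: list = field(default_factory=list)
    failed: bool = False

    @property
    def n_e(self) -> int:
        return self.traces["erosion"].selected

    @property
    def n_d(self) -> int:
        return self.traces["dilation"].selected


def dissect(
    shell: VoxelGrid,
    config: DissectionConfig | None = None,
    predictor: IterationPredictor | None = None,
) -> DissectionResult:
    """Run virtual dissection on a binary shell.

    With a ``predictor``, the erosion/dilation iteration counts are taken
    from the SVM prediction on the shell's shape features instead of the
    automatic index-based stopping rules (explicit ``config.n_e``/``n_d``
    still take precedence).
    """
    config = config or DissectionConfig()
    n_e, n_d = config.n_e, config.n_d
    if predictor is not None and n_e is None and n_d is None:
        n_e, n_d = predictor.predict(extract_features(shell))
    raw, traces = dissect_raw(
        shell,
        element=config.element,
        tau_e=config.tau_e,
        gamma=config.gamma,
        n_max=config.n_max,
        min_structure_volume=config.min_structure_volume,
        n_e=n_e,
        n_d=n_d,
    )
    classified = classify_structures(raw)
    if config.rescue:
        rescued = rescue_missed_structures(
            classified, min_structure_volume=config.min_structure_volume
        )
        if rescued is not classified:
            classified = classify_structures(rescued)
    planes: list = []
    refined = classified
    if config.refine and classified.structure_labels():
        refined, planes = refine_boundaries(classified, shell)
    return DissectionResult(
        labelmap=refined,
        raw_labelmap=classified,
        traces=traces,
        cut_planes=planes,
        failed=not classified.structure_labels(),
    )
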