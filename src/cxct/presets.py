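"""Named training configurations, including the published optimisation ladder.

``cx``, ``l2`` and ``perceptual`` are the three loss families compared in
the study; ``step1``–``step5`` retrace the parameter-search ladder that
arrived at the final configuration (step5 == cx):

=======  ============  =========  ================  =============================
preset   conv layers   width      feature sampling  loss
=======  ============  =========  ================  =============================
step1    17            64         65 x 65           L_CXs + L_CXt
step2    2             adaptive   65 x 65           L_CXs + L_CXt
step3    2             adaptive   65 x 65           L_CXs + L_CXt + ||G(s) - t||2
step4    2             adaptive   80 x 80           L_CXs + 5 L_CXt
step5    5             adaptive   80 x 80           L_CXs + 5 L_CXt
=======  ============  =========  ================  =============================

"adaptive" width means the generator's input-size rule (512 channels for
sides >= 128, else 1024) unless an explicit desk-scale width is supplied.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, Optional

from .cx_core import LossWeights
from .generator import GeneratorConfig, TrainConfig

__all__ = ["LossPreset", "PRESETS", "resolve_preset"]


@dataclass(frozen=True)
class LossPreset:
    name: str
    loss: str  # cx | l2 | perceptual | cx_l2
    lambda_weight: float = 5.0
    style_sample_n: int = 6400  # 80 x 80
    n_layers: int = 5
    base_width: Optional[int] = None  # None -> adaptive rule


PRESETS: Dict[str, LossPreset] = {
    "cx": LossPreset("cx", loss="cx", lambda_weight=5.0, style_sample_n=6400, n_layers=5),
    "l2": LossPreset("l2", loss="l2", n_layers=5),
    "perceptual": LossPreset("perceptual", loss="perceptual", n_layers=5),
    "step1": LossPreset("step1", loss="cx", lambda_weight=1.0, style_sample_n=65 * 65,
                        n_layers=17, base_width=64),
    "step2": LossPreset("step2", loss="cx", lambda_weight=1.0, style_sample_n=65 * 65,
                        n_layers=2),
    "step3": LossPreset("step3", loss="cx_l2", lambda_weight=1.0, style_sample_n=65 * 65,
                        n_layers=2),
    "step4": LossPreset("step4", loss="cx", lambda_weight=5.0, style_sample_n=6400,
                        n_layers=2),
    "step5": LossPreset("step5", loss="cx", lambda_weight=5.0, style_sample_n=6400,
                        n_layers=5),
}


def resolve_preset(
    name: str,
    base_train: TrainConfig = TrainConfig(),
    base_gen: GeneratorConfig = GeneratorConfig(),
    width_override: Optional[int] = None,
) -> tuple[TrainConfig, GeneratorConfig]:
    """Turn a preset name into concrete train/generator configurations."""
    if name not in PRESETS:
        raise ValueError(
            f"unknown preset {name!r}; available: {', '.join(sorted(PRESETS))}"
        )
    p = PRESETS[name]
    weights = replace(
        base_train.loss_weights,
        lambda_weight=p.lambda_weight,
        style_sample_n=p.style_sample_n,
    )
    train_cfg = replace(base_train, loss=p.loss, loss_weights=weights)
    width = width_override if width_override is not None else p.base_width
    gen_cfg = replace(base_gen, n_layers=p.n_layers, base_width=width)
    return train_cfg, gen_cfg
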