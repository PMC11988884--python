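"""The unit of data flowing through the pipeline: one labeled image.

Class order is fixed package-wide as ``(pes_planus, not_pes_planus)``;
``pes_planus`` is the positive (diagnosis) class everywhere, and argmax
ties in prediction resolve toward it.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

PES_PLANUS = "pes_planus"
NOT_PES_PLANUS = "not_pes_planus"

#: Fixed class order: positive class first.
CLASSES: tuple[str, str] = (PES_PLANUS, NOT_PES_PLANUS)

UNLABELED = "unlabeled"


@dataclass
class ImageSample:
    """One pixel array with its class label and patient identifier.

    Parameters
    ----------
    pixels
        ``(height, width)`` or ``(height, width, channels)`` float array
        with values in ``[0, 1]``.
    label
        One of :data:`CLASSES` or :data:`UNLABELED`.
    patient_id
        Opaque identifier used for patient-grouped data splits.
    meta
        Free-form extras (e.g. the generating arch angle of a synthetic
        image, or the source file path).
    """

    pixels: np.ndarray
    label: str = UNLABELED
    patient_id: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.label not in CLASSES and self.label != UNLABELED:
            raise ValueError(f"unknown label {self.label!r}")


def one_hot(labels, classes: tuple[str, ...] = CLASSES) -> np.ndarray:
    """One-hot target matrix in the fixed class order; rows sum to 1."""
    index = {c: i for i, c in enumerate(classes)}
    try:
        cols = [index[l] for l in labels]
    except KeyError as exc:  # pragma: no cover - message detail only
        raise ValueError(f"unknown label {exc.args[0]!r}") from exc
    T = np.zeros((len(cols), len(classes)))
    T[np.arange(len(cols)), cols] = 1.0
    return T
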