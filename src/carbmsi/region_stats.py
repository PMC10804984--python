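"""ROC/AUC discrimination of ion-image intensities between colony regions.

For each annotation, pixel intensities of its M+0 ion image are compared
between an isolated-colony mask and the interaction-zone mask.  The AUC is
the Mann-Whitney statistic: the probability that a random pixel from the
first mask outranks a random pixel from the second, ties credited 0.5.  Raw
intensities are used (no normalization), matching the default analysis; AUCs
are reported without multiple-testing correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .msi import IonImage, MSIDataset, RegionMask, extract_ion_image

__all__ = ["DiscriminationResult", "roc_auc", "discriminate_all"]


@dataclass(frozen=True)
class DiscriminationResult:
    metabolite: str
    comparison: str  # e.g. "f vs i"
    auc: float
    n_a: int
    n_b: int

    def __post_init__(self):
        if not (0.0 <= self.auc <= 1.0):
            raise ValueError("AUC must lie in [0, 1]")
        if min(self.n_a, self.n_b) < 1:
            raise ValueError("both masks must contribute at least one pixel")


def _mask_values(img: IonImage, mask: set[tuple[int, int]],
                 present: set[tuple[int, int]] | None) -> np.ndarray:
    pixels = mask if present is None else (mask & present)
    return np.array([img.values[y, x] for x, y in sorted(pixels)])


def roc_auc(img: IonImage,
            mask_a: set[tuple[int, int]],
            mask_b: set[tuple[int, int]],
            present: set[tuple[int, int]] | None = None) -> float:
    """Mann-Whitney AUC of image intensities, mask_a versus mask_b.

    AUC = (#pairs with value_a > value_b + 0.5 × ties) / (n_a × n_b).
    ``present`` optionally restricts both masks to pixels that carry spectra.
    """
    if not mask_a or not mask_b:
        raise ValueError("masks must be non-empty")
    if mask_a & mask_b:
        raise ValueError("masks overlap")
    a = _mask_values(img, mask_a, present)
    b = _mask_values(img, mask_b, present)
    if a.size == 0 or b.size == 0:
        raise ValueError("a mask has no pixels with spectra")
    u_a, _ = mannwhitneyu(a, b, alternative="two-sided")
    return float(u_a) / (a.size * b.size)


def discriminate_all(d: MSIDataset,
                     masks: RegionMask,
                     annotations,
                     tol_ppm: float = 3.0) -> pd.DataFrame:
    """AUC table (f vs i and b vs i) for every accepted M+0 annotation.

    ``annotations`` is an AnnotationResult or a list of accepted candidates.
    Pixels without spectra are excluded from the masks.  The table is sorted
    by each metabolite's strongest deviation from 0.5.
    """
    for label in ("f", "b", "i"):
        if label not in masks.regions:
            raise ValueError(f"region mask is missing required label {label!r}")
    masks.validate_grid(d.width, d.height)
    accepted = getattr(annotations, "accepted", annotations)
    present = d.present_pixels()
    rows = []
    seen = set()
    for c in accepted:
        if getattr(c, "br_mass_number", 79) != 79 or c.metabolite_id in seen:
            continue
        seen.add(c.metabolite_id)
        img = extract_ion_image(d, c.theoretical_mz, tol_ppm)
        for label in ("f", "b"):
            r = DiscriminationResult(
                metabolite=c.metabolite_id,
                comparison=f"{label} vs i",
                auc=roc_auc(img, masks[label], masks["i"], present),
                n_a=len(masks[label] & present),
                n_b=len(masks["i"] & present),
            )
            rows.append(r.__dict__)
    frame = pd.DataFrame(rows, columns=["metabolite", "comparison", "auc",
                                        "n_a", "n_b"])
    if len(frame):
        strength = frame.groupby("metabolite")["auc"].transform(
            lambda s: (s - 0.5).abs().max())
        frame = (frame.assign(_strength=strength)
                 .sort_values(["_strength", "metabolite", "comparison"],
                              ascending=[False, True, True])
                 .drop(columns="_strength")
                 .reset_index(drop=True))
    return frame
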