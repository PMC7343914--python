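"""Virtual cleaning: masked erasure and series subtraction.

The protocol removes the encrusting calcite computationally in two moves:

1. :func:`erase_masked` deletes the segmented specimen from a copy of the
   scan, leaving a *crust-only template* series;
2. :func:`subtract_template` compares the untouched original against that
   template — wherever the two agree the voxel belonged to crust or air
   and is set to a uniform background, wherever they differ the original
   HU value is kept.  The result is a series containing only the
   virtually cleaned specimen with its native intensities.

With the default fill value below the representable HU minimum the erase
can never coincide with a real voxel value, so the mask is recoverable
exactly from (original, template) and the round trip is bit-exact.
"""

from __future__ import annotations

import logging

import numpy as np

from .contours import BinaryMask
from .volume import CTVolume

__all__ = ["erase_masked", "subtract_template", "compute_masked_preview",
           "DEFAULT_FILL_HU", "DEFAULT_BACKGROUND_HU"]

logger = logging.getLogger(__name__)

DEFAULT_FILL_HU = -2048.0
DEFAULT_BACKGROUND_HU = -1024.0  # air


def _check_congruent(volume: CTVolume, other) -> None:
    shape = other.shape if not isinstance(other, CTVolume) else other.data.shape
    if volume.data.shape != tuple(shape):
        raise ValueError(f"grid shapes differ: {volume.data.shape} vs {tuple(shape)}")


def erase_masked(volume: CTVolume, mask: BinaryMask, fill_hu: float = DEFAULT_FILL_HU) -> CTVolume:
    """Erase the masked specimen, producing the crust-only template.

    Voxels where ``mask`` is true are set to ``fill_hu``; all others are
    bit-identical to the input.  The output carries the derivation tag
    ``"crust-template"``.
    """
    _check_congruent(volume, mask)
    coincident = int(np.count_nonzero(volume.data[mask.data] == fill_hu))
    if coincident:
        logger.warning(
            "%d masked voxels already equal fill_hu=%g; they will not be "
            "recoverable by subtraction", coincident, fill_hu,
        )
    data = volume.data.copy()
    data[mask.data] = fill_hu
    out = volume.copy(data=data, tag="crust-template")
    out.series_meta["fill_hu"] = float(fill_hu)
    out.series_meta["coincidence_voxels"] = coincident
    return out


def subtract_template(
    original: CTVolume, template: CTVolume, background_hu: float = DEFAULT_BACKGROUND_HU
) -> CTVolume:
    """Subtract the crust template from the untouched original series.

    Wherever original and template agree the voxel is outside the erased
    region: it is set to ``background_hu``.  Wherever they differ, the
    original HU value is kept.  The result shows only the virtually
    cleaned specimen (tag ``"virtually-cleaned"``).

    Voxelwise arithmetic subtraction would leave HU *offsets*; the
    difference-support semantics used here is what actually produces a
    series containing only the specimen.

    A template whose difference support holds values other than a single
    fill value cannot have come from one masked erase; this is reported
    as a warning with the offending voxel count.
    """
    _check_congruent(original, template)
    diff = original.data != template.data
    fill_values = np.unique(template.data[diff])
    if len(fill_values) > 1:
        expected = template.series_meta.get("fill_hu")
        bad = diff & (template.data != (fill_values[0] if expected is None else expected))
        logger.warning(
            "template is not consistent with a single masked erase: "
            "%d voxels deviate from a uniform fill value", int(bad.sum()),
        )
    data = np.where(diff, original.data, background_hu)
    out = original.copy(data=data, tag="virtually-cleaned")
    out.series_meta["background_hu"] = float(background_hu)
    return out


def compute_masked_preview(volume: CTVolume, mask: BinaryMask,
                           background_hu: float = DEFAULT_BACKGROUND_HU) -> CTVolume:
    """Mask-applied extraction for a first visual inspection.

    Identical mathematics to the erase/subtract round trip (original HU
    inside the mask, uniform background outside), in one step.
    """
    _check_congruent(volume, mask)
    data = np.where(mask.data, volume.data, background_hu)
    return volume.copy(data=data, tag="masked-preview")
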