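"""Colour-channel unmixing for Oil Red O + haematoxylin bright-field images.

Oil Red O stains neutral lipid red; haematoxylin stains nuclei blue-purple.
The conversion to a two-channel image is a plain RGB-space bias difference:

    lipid  = max(0, R - max(G, B))    (red bias)
    nuclei = max(0, B - max(R, G))    (blue bias)

Subtracting the maximum of the other two channels makes neutral grey/white
background cancel exactly and attenuates the bias wherever red and blue
co-occur (purple overlap), which is why colorimetric scores run somewhat
below their fluorescence counterparts.  Optical-density (Beer-Lambert)
stain deconvolution is deliberately not used here; the pipeline's contract
is the simple difference image.  Users wanting orthodox stain separation
can pre-process with e.g. scikit-image's ``separate_stains`` and feed the
result in as fluorescence channels.
"""

from __future__ import annotations

import numpy as np

from .core import PixelGrid, RgbImage, TwoChannelImage


def unmix_oro_haematoxylin(rgb: RgbImage) -> TwoChannelImage:
    """Convert an ORO/haematoxylin RGB image to (nuclei, lipid) channels."""
    dtype = rgb.red.values.dtype
    r = rgb.red.values.astype(np.int64)
    g = rgb.green.values.astype(np.int64)
    b = rgb.blue.values.astype(np.int64)
    lipid = np.clip(r - np.maximum(g, b), 0, None).astype(dtype)
    nuclei = np.clip(b - np.maximum(r, g), 0, None).astype(dtype)
    pitch = rgb.pixel_pitch_um
    return TwoChannelImage(
        nuclei=PixelGrid(nuclei, pitch), lipid=PixelGrid(lipid, pitch)
    )
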