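"""Shared class-code and colour conventions for the four-class tissue scheme.

Every module that touches labels imports these, so the phantom generator, the
labeling tool and the map renderers can never drift apart.
"""

from __future__ import annotations

# Integer label codes used in gold-standard maps and training datasets.
UNLABELED = 0
NORMAL = 1
TUMOR = 2
VESSEL = 3
BACKGROUND = 4

#: Class codes that may appear as actual tissue/background labels, in the
#: canonical order used for probability vectors and density vectors.
CLASS_CODES = (NORMAL, TUMOR, VESSEL, BACKGROUND)

CLASS_NAMES = {
    UNLABELED: "unlabeled",
    NORMAL: "normal",
    TUMOR: "tumor",
    VESSEL: "vessel",
    BACKGROUND: "background",
}

#: Display colours (RGB in [0, 1]): normal green, tumor red, vessel blue,
#: background black.  A white-background variant is available via config.
CLASS_COLORS = {
    NORMAL: (0.0, 1.0, 0.0),
    TUMOR: (1.0, 0.0, 0.0),
    VESSEL: (0.0, 0.0, 1.0),
    BACKGROUND: (0.0, 0.0, 0.0),
}

#: Majority-vote tie-break priority: missing tumor is the costly error, so a
#: tied cluster goes to tumor first, then vessel, then normal, then background.
TIE_PRIORITY = (TUMOR, VESSEL, NORMAL, BACKGROUND)

#: Default synthetic-RGB wavelength triplet (nm) for VNIR cubes; matches the
#: band choices of the manufacturer's acquisition software.
VNIR_RGB_TRIPLET_NM = (708.97, 539.44, 479.06)

#: VNIR across-track pixel pitch in micrometres.
VNIR_PIXEL_PITCH_UM = 128.7
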