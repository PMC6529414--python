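"""Tissue class labels used by the phantom generator and the segmentation stage.

Priority (highest wins when structures overlap during phantom painting):
probe metal > calcification > cavity > vessel > cell > tissue.
"""

from enum import IntEnum


class TissueClass(IntEnum):
    TISSUE = 0
    VESSEL = 1
    CELL = 2
    PROBE_METAL = 3
    CALCIFICATION = 4
    CAVITY = 5
    EXCLUDED = 6


#: Painting order for the phantom: later entries overwrite earlier ones.
PAINT_ORDER = (
    TissueClass.CELL,
    TissueClass.VESSEL,
    TissueClass.CAVITY,
    TissueClass.CALCIFICATION,
    TissueClass.PROBE_METAL,
)

DEFAULT_CLASS_TABLE = {int(c): c.name.lower() for c in TissueClass}
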