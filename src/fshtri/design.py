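"""Design constants shared across the pipeline.

The experiment crosses a gonadotropin treatment (Fsh) with trilostane
(Tri), an inhibitor of 3beta-hydroxysteroid dehydrogenase that blocks
Delta4-steroid synthesis.  Four treatment groups result: Ctrl, Fsh, Tri
and FshTri.  Comparing the Fsh response in the absence (Fsh - Ctrl) and
presence (FshTri - Tri) of the inhibitor separates steroid-mediated from
steroid-independent hormone action, and each responsive clone is assigned
to one of the response classes below.
"""

from __future__ import annotations

import numpy as np

#: Treatment groups of the 2x2 hormone x inhibitor design, in display order.
GROUPS: tuple[str, ...] = ("Ctrl", "Fsh", "Tri", "FshTri")

#: Response classes a clone can be planted with / assigned to.
RESPONSE_CLASSES: tuple[str, ...] = (
    "null",
    "mediated_abolished",
    "mediated_reduced",
    "independent_up",
    "cooperative",
    "antagonistic",
    "independent_down",
)

#: Conventional heatmap-cluster codes for the response classes.
CLUSTER_CODES: dict[str, str] = {
    "mediated_abolished": "1a",
    "mediated_reduced": "1b",
    "independent_up": "2",
    "cooperative": "3",
    "antagonistic": "4",
    "independent_down": "5",
    "null": "-",
    "unclassified": "-",
}

#: Standard pairwise contrasts, written (reference, treated) so that the
#: effect is treated minus reference on the log2 scale.
FSH_VS_CTRL = ("Ctrl", "Fsh")
FSHTRI_VS_TRI = ("Tri", "FshTri")
TRI_VS_CTRL = ("Ctrl", "Tri")

# Log2 group-mean offsets from baseline for (Ctrl, Fsh, Tri, FshTri),
# per unit planted effect.  These encode the class semantics:
#   mediated_abolished : Fsh response present, gone under the inhibitor
#   mediated_reduced   : Fsh response halved under the inhibitor
#   independent_up/down: Fsh response unchanged by the inhibitor
#   cooperative        : inhibitor lowers basal level, Fsh-stimulated
#                        level unaffected (steroids and Fsh act alike)
#   antagonistic       : no direct Fsh effect; inhibitor raises basal and
#                        unmasks an Fsh response
_PATTERNS: dict[str, tuple[float, float, float, float]] = {
    "null": (0.0, 0.0, 0.0, 0.0),
    "mediated_abolished": (0.0, 1.0, 0.0, 0.0),
    "mediated_reduced": (0.0, 1.0, 0.0, 0.5),
    "independent_up": (0.0, 1.0, 0.0, 1.0),
    "independent_down": (0.0, -1.0, 0.0, -1.0),
    "cooperative": (0.0, 1.0, -1.0, 1.0),
    "antagonistic": (0.0, 0.0, 1.0, 2.0),
}


def class_pattern(label: str, effect: float = 1.0) -> np.ndarray:
    """Log2 group-mean offsets (Ctrl, Fsh, Tri, FshTri) for a response class.

    Parameters
    ----------
    label:
        One of :data:`RESPONSE_CLASSES`.
    effect:
        Magnitude of the planted treatment effect on the log2 scale.
    """
    try:
        base = _PATTERNS[label]
    except KeyError:
        raise ValueError(f"unknown response class {label!r}") from None
    return effect * np.asarray(base, dtype=float)
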