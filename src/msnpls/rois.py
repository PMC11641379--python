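"""Canonical parcellation and feature-name constants.

The pipeline operates on the 34 left-hemisphere cortical regions of the
Desikan-Killiany atlas.  Input tables are always reindexed to this order and
unknown region labels are a hard error, so every downstream matrix has a
fixed, reproducible row order.
"""

from __future__ import annotations

#: The 34 left-hemisphere Desikan-Killiany cortical regions, in the
#: conventional FreeSurfer ordering.
DESIKAN_KILLIANY_LH: tuple[str, ...] = (
    "bankssts",
    "caudalanteriorcingulate",
    "caudalmiddlefrontal",
    "cuneus",
    "entorhinal",
    "fusiform",
    "inferiorparietal",
    "inferiortemporal",
    "isthmuscingulate",
    "lateraloccipital",
    "lateralorbitofrontal",
    "lingual",
    "medialorbitofrontal",
    "middletemporal",
    "parahippocampal",
    "paracentral",
    "parsopercularis",
    "parsorbitalis",
    "parstriangularis",
    "pericalcarine",
    "postcentral",
    "posteriorcingulate",
    "precentral",
    "precuneus",
    "rostralanteriorcingulate",
    "rostralmiddlefrontal",
    "superiorfrontal",
    "superiorparietal",
    "superiortemporal",
    "supramarginal",
    "frontalpole",
    "temporalpole",
    "transversetemporal",
    "insula",
)

N_ROIS = len(DESIKAN_KILLIANY_LH)

#: The 13 regional features: seven T1w morphometric descriptors and six
#: diffusion-tensor microstructural descriptors (mean/radial diffusivity,
#: fractional anisotropy and the three tensor eigenvalues).
FEATURE_NAMES: tuple[str, ...] = (
    "area",
    "fold_index",
    "curvature_index",
    "gaussian_curvature",
    "mean_curvature",
    "thickness",
    "volume",
    "MD",
    "RD",
    "FA",
    "L1",
    "L2",
    "L3",
)

N_FEATURES = len(FEATURE_NAMES)
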