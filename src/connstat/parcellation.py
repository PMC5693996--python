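"""The 90-region AAL cerebral parcellation used for whole-brain networks.

Region-of-interest networks here are built on the automated anatomical
labeling (AAL) atlas restricted to the cerebrum: 40 cortical and 5
subcortical regions per hemisphere, 90 regions in all.  Labels follow the
conventional AAL short codes (``Frontal_Sup_Orb_L`` etc.); a set of
descriptive aliases covers the long anatomical names commonly used in
clinical tables (e.g. "left superior frontal gyrus, pars orbitalis").
"""

from __future__ import annotations

import re

# Standard AAL-90 ordering: left/right interleaved, cortex first, then the
# deep grey nuclei, then temporal cortex.
AAL90_LABELS: tuple[str, ...] = (
    "Precentral_L", "Precentral_R",
    "Frontal_Sup_L", "Frontal_Sup_R",
    "Frontal_Sup_Orb_L", "Frontal_Sup_Orb_R",
    "Frontal_Mid_L", "Frontal_Mid_R",
    "Frontal_Mid_Orb_L", "Frontal_Mid_Orb_R",
    "Frontal_Inf_Oper_L", "Frontal_Inf_Oper_R",
    "Frontal_Inf_Tri_L", "Frontal_Inf_Tri_R",
    "Frontal_Inf_Orb_L", "Frontal_Inf_Orb_R",
    "Rolandic_Oper_L", "Rolandic_Oper_R",
    "Supp_Motor_Area_L", "Supp_Motor_Area_R",
    "Olfactory_L", "Olfactory_R",
    "Frontal_Sup_Medial_L", "Frontal_Sup_Medial_R",
    "Frontal_Med_Orb_L", "Frontal_Med_Orb_R",
    "Rectus_L", "Rectus_R",
    "Insula_L", "Insula_R",
    "Cingulum_Ant_L", "Cingulum_Ant_R",
    "Cingulum_Mid_L", "Cingulum_Mid_R",
    "Cingulum_Post_L", "Cingulum_Post_R",
    "Hippocampus_L", "Hippocampus_R",
    "ParaHippocampal_L", "ParaHippocampal_R",
    "Amygdala_L", "Amygdala_R",
    "Calcarine_L", "Calcarine_R",
    "Cuneus_L", "Cuneus_R",
    "Lingual_L", "Lingual_R",
    "Occipital_Sup_L", "Occipital_Sup_R",
    "Occipital_Mid_L", "Occipital_Mid_R",
    "Occipital_Inf_L", "Occipital_Inf_R",
    "Fusiform_L", "Fusiform_R",
    "Postcentral_L", "Postcentral_R",
    "Parietal_Sup_L", "Parietal_Sup_R",
    "Parietal_Inf_L", "Parietal_Inf_R",
    "SupraMarginal_L", "SupraMarginal_R",
    "Angular_L", "Angular_R",
    "Precuneus_L", "Precuneus_R",
    "Paracentral_Lobule_L", "Paracentral_Lobule_R",
    "Caudate_L", "Caudate_R",
    "Putamen_L", "Putamen_R",
    "Pallidum_L", "Pallidum_R",
    "Thalamus_L", "Thalamus_R",
    "Heschl_L", "Heschl_R",
    "Temporal_Sup_L", "Temporal_Sup_R",
    "Temporal_Pole_Sup_L", "Temporal_Pole_Sup_R",
    "Temporal_Mid_L", "Temporal_Mid_R",
    "Temporal_Pole_Mid_L", "Temporal_Pole_Mid_R",
    "Temporal_Inf_L", "Temporal_Inf_R",
)

N_REGIONS = len(AAL90_LABELS)

# Deep grey nuclei counted as the 5 subcortical ROIs per hemisphere; the
# remaining 40 per hemisphere (including limbic/medial-temporal cortex)
# are counted as cortical.
SUBCORTICAL_STEMS = frozenset(
    {"Caudate", "Putamen", "Pallidum", "Thalamus", "Amygdala"}
)

# Long anatomical names -> AAL codes, for regions that commonly appear
# spelled out in clinical tables.
_DESCRIPTIVE_ALIASES: dict[str, str] = {
    "left superior frontal gyrus, pars orbitalis": "Frontal_Sup_Orb_L",
    "right superior frontal gyrus, pars orbitalis": "Frontal_Sup_Orb_R",
    "left middle frontal gyrus, pars orbitalis": "Frontal_Mid_Orb_L",
    "right middle frontal gyrus, pars orbitalis": "Frontal_Mid_Orb_R",
    "left olfactory cortex": "Olfactory_L",
    "right olfactory cortex": "Olfactory_R",
    "left caudate": "Caudate_L",
    "right caudate": "Caudate_R",
    "left putamen": "Putamen_L",
    "right putamen": "Putamen_R",
    "left pallidum": "Pallidum_L",
    "right pallidum": "Pallidum_R",
    "left thalamus": "Thalamus_L",
    "right thalamus": "Thalamus_R",
    "left middle temporal gyrus": "Temporal_Mid_L",
    "right middle temporal gyrus": "Temporal_Mid_R",
    "left postcentral gyrus": "Postcentral_L",
    "right postcentral gyrus": "Postcentral_R",
    "left amygdala": "Amygdala_L",
    "right amygdala": "Amygdala_R",
}


def _normalize(label: str) -> str:
    """Lower-case and collapse whitespace/underscores/hyphens/commas."""
    return re.sub(r"[\s_,\-]+", " ", label.strip().lower())


_CANONICAL: dict[str, str] = {_normalize(lab): lab for lab in AAL90_LABELS}
_CANONICAL.update({_normalize(k): v for k, v in _DESCRIPTIVE_ALIASES.items()})

_INDEX: dict[str, int] = {lab: i for i, lab in enumerate(AAL90_LABELS)}


def canonicalize(label: str) -> str:
    """Map a region name (AAL code or descriptive alias, any case or
    separator style) to its canonical AAL label.

    Raises
    ------
    KeyError
        If the name matches no AAL-90 region.
    """
    key = _normalize(label)
    try:
        return _CANONICAL[key]
    except KeyError:
        raise KeyError(f"unknown parcellation region: {label!r}") from None


def label_index(label: str) -> int:
    """Position of a region in the canonical AAL-90 ordering."""
    return _INDEX[canonicalize(label)]


def is_subcortical(label: str) -> bool:
    stem = canonicalize(label).rsplit("_", 1)[0]
    return stem in SUBCORTICAL_STEMS


def hemisphere_counts() -> dict[str, dict[str, int]]:
    """Cortical/subcortical region counts per hemisphere."""
    counts = {"L": {"cortical": 0, "subcortical": 0},
              "R": {"cortical": 0, "subcortical": 0}}
    for lab in AAL90_LABELS:
        hemi = lab.rsplit("_", 1)[1]
        kind = "subcortical" if is_subcortical(lab) else "cortical"
        counts[hemi][kind] += 1
    return counts


def generic_labels(n: int) -> tuple[str, ...]:
    """Synthetic region labels (``roi_00`` ...) for reduced parcellations."""
    width = max(2, len(str(n - 1)))
    return tuple(f"roi_{i:0{width}d}" for i in range(n))
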