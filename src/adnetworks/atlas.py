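"""Default 90-region cerebral parcellation and its lobe/hemisphere map.

Network nodes follow the 90-region automated anatomical labeling (AAL)
convention used throughout resting-state connectomics: 45 homologous region
pairs covering the cerebrum (cerebellum excluded), each carried as a
left/right pair.  The grouping of regions into five lobar divisions
(frontal, parietal, occipital, temporal, subcortical) is a convention, not
an anatomical ground truth: atlases differ on where to place limbic and
paralimbic structures.  Here the cingulate is split anterior+middle →
frontal, posterior → parietal; the medial temporal structures
(hippocampus, parahippocampus, amygdala) and the fusiform gyrus go with
the temporal lobe; the insula joins the subcortical division.  Users with
a different convention can pass their own map to any function that takes
one.
"""

from __future__ import annotations

import pandas as pd

LOBES = ("frontal", "parietal", "occipital", "temporal", "subcortical")
HEMISPHERES = ("L", "R")

# 45 region pairs: (base name, lobe).  Expanded L/R below in pair order,
# left first, mirroring the interleaved ordering of the AAL atlas.
_REGION_PAIRS = [
    ("Precentral", "frontal"),
    ("Frontal_Sup", "frontal"),
    ("Frontal_Sup_Orb", "frontal"),
    ("Frontal_Mid", "frontal"),
    ("Frontal_Mid_Orb", "frontal"),
    ("Frontal_Inf_Oper", "frontal"),
    ("Frontal_Inf_Tri", "frontal"),
    ("Frontal_Inf_Orb", "frontal"),
    ("Rolandic_Oper", "frontal"),
    ("Supp_Motor_Area", "frontal"),
    ("Olfactory", "frontal"),
    ("Frontal_Sup_Medial", "frontal"),
    ("Frontal_Med_Orb", "frontal"),
    ("Rectus", "frontal"),
    ("Insula", "subcortical"),
    ("Cingulum_Ant", "frontal"),
    ("Cingulum_Mid", "frontal"),
    ("Cingulum_Post", "parietal"),
    ("Hippocampus", "temporal"),
    ("ParaHippocampal", "temporal"),
    ("Amygdala", "temporal"),
    ("Calcarine", "occipital"),
    ("Cuneus", "occipital"),
    ("Lingual", "occipital"),
    ("Occipital_Sup", "occipital"),
    ("Occipital_Mid", "occipital"),
    ("Occipital_Inf", "occipital"),
    ("Fusiform", "temporal"),
    ("Postcentral", "parietal"),
    ("Parietal_Sup", "parietal"),
    ("Parietal_Inf", "parietal"),
    ("SupraMarginal", "parietal"),
    ("Angular", "parietal"),
    ("Precuneus", "parietal"),
    ("Paracentral_Lobule", "frontal"),
    ("Caudate", "subcortical"),
    ("Putamen", "subcortical"),
    ("Pallidum", "subcortical"),
    ("Thalamus", "subcortical"),
    ("Heschl", "temporal"),
    ("Temporal_Sup", "temporal"),
    ("Temporal_Pole_Sup", "temporal"),
    ("Temporal_Mid", "temporal"),
    ("Temporal_Pole_Mid", "temporal"),
    ("Temporal_Inf", "temporal"),
]

def default_lobe_map() -> pd.DataFrame:
    """Return the shipped region table.

    Columns: ``region`` (e.g. ``Precuneus_L``), ``lobe``, ``hemisphere``,
    indexed 0..89 in atlas order (left/right interleaved).
    """
    rows = []
    for base, lobe in _REGION_PAIRS:
        for hemi in HEMISPHERES:
            rows.append({"region": f"{base}_{hemi}", "lobe": lobe, "hemisphere": hemi})
    return pd.DataFrame(rows)


def default_region_ids() -> list[str]:
    return default_lobe_map()["region"].tolist()


def validate_lobe_map(lobe_map: pd.DataFrame, region_ids: list[str]) -> None:
    """Check that every region is mapped exactly once to a known lobe."""
    mapped = set(lobe_map["region"])
    missing = [r for r in region_ids if r not in mapped]
    if missing:
        raise KeyError(f"regions missing from lobe map: {missing[:5]}")
    if lobe_map["region"].duplicated().any():
        dups = lobe_map.loc[lobe_map["region"].duplicated(), "region"].tolist()
        raise ValueError(f"regions mapped more than once: {dups[:5]}")
    bad = set(lobe_map["lobe"]) - set(LOBES)
    if bad:
        raise ValueError(f"unknown lobe labels: {sorted(bad)}")
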