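"""The frozen feature manifest: names, families and transform applicability.

The manifest is the testable contract of the extractor: 18 statistical,
38 histogram-based and 95 texture features on each of the ten images
(base, eight stationary-wavelet, one LoG) plus 28 morphological features
on the base image only — 1538 features per ROI.
"""

from __future__ import annotations

from ..image_filters import WAVELET_LABELS
from .statistical import STATISTICAL_NAMES
from .histogram import HISTOGRAM_NAMES
from .texture import TEXTURE_NAMES
from .morphology import MORPHOLOGY_NAMES

__all__ = ["FAMILY_COUNTS", "ALL_TRANSFORMS", "feature_manifest",
           "expanded_feature_names", "TOTAL_FEATURES"]

FAMILY_COUNTS = {"statistical": 18, "histogram": 38, "texture": 95,
                 "morphology": 28}
ALL_TRANSFORMS = ("base",) + tuple(f"wav_{w}" for w in WAVELET_LABELS) + ("log",)
TOTAL_FEATURES = (18 + 38 + 95) * 10 + 28  # = 1538

_FAMILY_NAMES = {
    "statistical": tuple(f"stat_{n}" for n in STATISTICAL_NAMES),
    "histogram": HISTOGRAM_NAMES,
    "texture": TEXTURE_NAMES,
    "morphology": MORPHOLOGY_NAMES,
}

assert all(len(_FAMILY_NAMES[f]) == c for f, c in FAMILY_COUNTS.items())


def feature_manifest() -> list[tuple[str, str, str]]:
    """(name, family, applicability) for every base feature.

    Applicability is ``"all"`` for intensity families (computed on every
    transform) and ``"base"`` for morphology.
    """
    rows = []
    for fam in ("statistical", "histogram", "texture"):
        rows += [(n, fam, "all") for n in _FAMILY_NAMES[fam]]
    rows += [(n, "morphology", "base") for n in _FAMILY_NAMES["morphology"]]
    return rows


def expanded_feature_names(
        transforms: tuple[str, ...] = ALL_TRANSFORMS,
        families: tuple[str, ...] = ("statistical", "histogram",
                                     "texture", "morphology"),
) -> list[str]:
    """Column names of the feature table: ``<transform>_<feature>``.

    Morphology appears once, prefixed ``base_``.  With the full transform
    and family sets the list has exactly 1538 entries.
    """
    names: list[str] = []
    for t in transforms:
        for fam in families:
            if fam == "morphology":
                continue
            names += [f"{t}_{n}" for n in _FAMILY_NAMES[fam]]
    if "morphology" in families and "base" in transforms:
        names += [f"base_{n}" for n in _FAMILY_NAMES["morphology"]]
    return names


def write_manifest_tsv(path) -> None:
    """Write the manifest as a plain-text table (name, family, applies_to)."""
    with open(path, "w") as fh:
        fh.write("feature\tfamily\tapplies_to\n")
        for name, fam, app in feature_manifest():
            fh.write(f"{name}\t{fam}\t{app}\n")
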