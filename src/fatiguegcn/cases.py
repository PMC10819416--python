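"""The four classification cases over the five ordinal fatigue classes.

Case I is the binary normal vs full-fatigue problem; each subsequent case
adds the next-nearest fatigue stage, ending with all five classes in
case IV.  The subsets are nested (I within II within III within IV), and
labels are remapped to 0..K-1 in subset order for training.
"""

from __future__ import annotations

from dataclasses import dataclass

from .containers import WindowedDataset

__all__ = ["CaseDefinition", "CASE_SUBSETS", "define_case", "select_case"]

CASE_SUBSETS: dict[str, tuple[int, ...]] = {
    "I": (0, 4),
    "II": (0, 3, 4),
    "III": (0, 2, 3, 4),
    "IV": (0, 1, 2, 3, 4),
}


@dataclass(frozen=True)
class CaseDefinition:
    case_id: str
    class_subset: tuple[int, ...]

    @property
    def n_classes(self) -> int:
        return len(self.class_subset)


def define_case(case_id: str) -> CaseDefinition:
    subset = CASE_SUBSETS.get(str(case_id).upper())
    if subset is None:
        raise ValueError(f"unknown case {case_id!r}; expected one of {list(CASE_SUBSETS)}")
    return CaseDefinition(str(case_id).upper(), subset)


def select_case(ds: WindowedDataset, case: CaseDefinition | str) -> WindowedDataset:
    """Filter a cohort to a case's classes, relabeling to 0..K-1 in subset order."""
    if isinstance(case, str):
        case = define_case(case)
    return ds.class_subset(case.class_subset, relabel=True)
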