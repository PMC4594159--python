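"""Per-cell focus statistics: focus-to-cell assignment and count distributions.

Cells touching the image border are excluded from all distribution summaries
(they may be truncated by the field of view). "Single" cells are labels whose
one-pixel dilation touches no other label and which do not touch the border;
this automates the manual isolated-cell subset selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy.ndimage import binary_dilation, find_objects, generate_binary_structure

from .containers import Focus, LabelMask


@dataclass
class PerCellCounts:
    counts: dict[int, int]
    is_single: dict[int, bool]
    touches_border: dict[int, bool]
    discarded: list[Focus] = dc_field(default_factory=list)

    @property
    def n_assigned(self) -> int:
        return sum(self.counts.values())

    def labels(self, subset: str = "all", include_border: bool = False) -> list[int]:
        out = []
        for lab in self.counts:
            if not include_border and self.touches_border.get(lab, False):
                continue
            if subset == "single" and not self.is_single.get(lab, False):
                continue
            out.append(lab)
        return out


@dataclass
class DistributionSummary:
    mean_foci_per_cell: float
    histogram: dict[str, float]  # fractions over {"0", "1", "2", "3+"}
    frac_at_least_one: float
    n_cells: int
    raw_counts: dict[int, int] = dc_field(default_factory=dict)  # count -> n_cells


def identify_single_cells(mask: LabelMask) -> set[int]:
    """Labels with no touching neighbour and no border contact.

    A label is single iff its dilation by a 1-px diamond overlaps no other
    label and the label does not touch the image border.
    """
    labels = mask.plane_labels()
    se = generate_binary_structure(2, 1)  # diamond of radius 1
    singles: set[int] = set()
    slices = find_objects(labels)
    for lab_idx, sl in enumerate(slices, start=1):
        if sl is None:
            continue
        # expand the bounding box by 1 px for the dilation
        r0 = max(sl[0].start - 1, 0)
        r1 = min(sl[0].stop + 1, labels.shape[0])
        c0 = max(sl[1].start - 1, 0)
        c1 = min(sl[1].stop + 1, labels.shape[1])
        sub = labels[r0:r1, c0:c1]
        own = sub == lab_idx
        if not own.any():
            continue
        if (sl[0].start == 0 or sl[1].start == 0
                or sl[0].stop == labels.shape[0] or sl[1].stop == labels.shape[1]):
            continue  # touches border
        grown = binary_dilation(own, structure=se)
        neighbours = sub[grown & ~own]
        if np.any((neighbours != 0) & (neighbours != lab_idx)):
            continue
        singles.add(lab_idx)
    return singles


def _touches_border(labels: np.ndarray) -> set[int]:
    edge = np.concatenate([labels[0, :], labels[-1, :],
                           labels[:, 0], labels[:, -1]])
    return set(int(v) for v in np.unique(edge) if v > 0)


def assign_foci(mask: LabelMask, foci: list[Focus]) -> PerCellCounts:
    """Assign each focus to the cell under its rounded centroid pixel.

    A focus landing on background is rescued to a cell present within a 1-px
    (diamond) neighbourhood if that cell is unique; otherwise it is discarded
    and reported. Conservation: assigned + discarded = input foci.
    """
    labels = mask.plane_labels()
    h, w = labels.shape
    label_values = [int(v) for v in np.unique(labels) if v > 0]
    counts = {lab: 0 for lab in label_values}
    border = _touches_border(labels)
    singles = identify_single_cells(mask)
    discarded: list[Focus] = []
    for f in foci:
        r, c = int(round(f.y)), int(round(f.x))
        if not (0 <= r < h and 0 <= c < w):
            discarded.append(f)
            continue
        lab = int(labels[r, c])
        if lab == 0:
            neigh = set()
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < h and 0 <= cc < w and labels[rr, cc] > 0:
                        neigh.add(int(labels[rr, cc]))
            if len(neigh) == 1:
                lab = neigh.pop()
            else:
                discarded.append(f)
                continue
        counts[lab] += 1
    return PerCellCounts(
        counts=counts,
        is_single={lab: lab in singles for lab in label_values},
        touches_border={lab: lab in border for lab in label_values},
        discarded=discarded,
    )


def distribution_summary(counts: PerCellCounts, subset: str = "all",
                         include_border: bool = False) -> DistributionSummary:
    """Mean foci/cell and the {0, 1, 2, 3+} focus-count distribution.

    ``subset="single"`` restricts to isolated single cells. Border-touching
    cells are excluded unless ``include_border`` is set.
    """
    if subset not in ("all", "single"):
        raise ValueError("subset must be 'all' or 'single'")
    labs = counts.labels(subset=subset, include_border=include_border)
    if not labs:
        raise ValueError(f"no cells in subset {subset!r}")
    vals = np.array([counts.counts[lab] for lab in labs], dtype=int)
    return summarize_counts(vals)


def summarize_counts(vals: np.ndarray) -> DistributionSummary:
    """Distribution summary from a raw vector of per-cell focus counts."""
    vals = np.asarray(vals, dtype=int)
    if vals.size == 0:
        raise ValueError("empty count vector")
    n = vals.size
    hist = {
        "0": float(np.mean(vals == 0)),
        "1": float(np.mean(vals == 1)),
        "2": float(np.mean(vals == 2)),
        "3+": float(np.mean(vals >= 3)),
    }
    raw: dict[int, int] = {int(k): int(v) for k, v in
                           zip(*np.unique(vals, return_counts=True))}
    return DistributionSummary(
        mean_foci_per_cell=float(vals.mean()),
        histogram=hist,
        frac_at_least_one=float(np.mean(vals >= 1)),
        n_cells=int(n),
        raw_counts=raw,
    )
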