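"""Lipid directors, tilt statistics and orientational order parameters.

A lipid's *director* is the unit vector from its head bead to the mean of
its terminal bead(s) — a single-molecule orientation.  Its *tilt* is the
angle between the director and the membrane normal (the z axis), folded
to [0°, 90°].  Chain ordering is quantified by the second-rank order
parameter

    P2 = ⟨ (3 cos²θ − 1) / 2 ⟩

averaged over inter-bead bond vectors, with θ measured either against
the membrane normal (sensitive to both molecular tilt and conformational
disorder) or against each lipid's own director ("renormalized" P2, which
isolates conformational disorder from tilt).  P2 = 1 means perfect
alignment with the reference axis, −0.5 perfect perpendicular order, and
0 an isotropic distribution.

Inter-layer cooperativity of the tilt field is measured by laterally
segmenting the layers and correlating tilt magnitudes of lipid pairs in
the same segment across two layers.
"""

from __future__ import annotations

import math
from collections.abc import Sequence

import numpy as np

from .datatypes import DirectorField, LipidConfiguration, OrderParameterResult, TiltHistogram
from .errors import (
    DegenerateBondError,
    DegenerateLipidError,
    InvalidParameterError,
    UndefinedCorrelationError,
)


def compute_directors(
    config: LipidConfiguration, method: str = "head_to_tail"
) -> DirectorField:
    """Per-lipid orientation vectors.

    ``method="head_to_tail"`` (default): unit vector from the head bead
    to the mean of the terminal bead(s).  ``method="principal_axis"``:
    leading principal axis of the lipid's bead cloud, oriented from head
    toward tail.  Either way the vector is flipped so its z-component is
    nonnegative, defining tilt on [0°, 90°].
    """
    config.validate_lipids()
    lids, inverse = np.unique(config.lipid_id, return_inverse=True)
    n_lip = len(lids)

    head_mask = config.bead_role == "head"
    # one head per lipid (validated); heads indexed by lipid via inverse
    bases = np.empty((n_lip, 3))
    bases[inverse[head_mask]] = config.bead_positions[head_mask]
    layers = np.empty(n_lip, dtype=int)
    layers[inverse[head_mask]] = config.layer_index[head_mask]

    term_mask = config.bead_role == "terminal"
    term_sum = np.zeros((n_lip, 3))
    np.add.at(term_sum, inverse[term_mask], config.bead_positions[term_mask])
    term_count = np.bincount(inverse[term_mask], minlength=n_lip)
    term_mean = term_sum / term_count[:, None]

    if method == "head_to_tail":
        vectors = term_mean - bases
    elif method == "principal_axis":
        order = np.argsort(config.lipid_id, kind="stable")
        starts = np.searchsorted(config.lipid_id[order], lids)
        bounds = np.append(starts, len(order))
        vectors = np.empty((n_lip, 3))
        for i in range(n_lip):
            pos = config.bead_positions[order[bounds[i] : bounds[i + 1]]]
            centered = pos - pos.mean(axis=0)
            _, _, vt = np.linalg.svd(centered, full_matrices=False)
            v = vt[0]
            if np.dot(v, term_mean[i] - bases[i]) < 0:  # orient head -> tail
                v = -v
            vectors[i] = v
    else:
        raise InvalidParameterError(f"unknown director method {method!r}")

    norms = np.linalg.norm(vectors, axis=1)
    if np.any(norms < 1e-12):
        bad = lids[np.argmax(norms < 1e-12)]
        raise DegenerateLipidError(f"lipid {bad} has a zero-length head-to-tail vector")
    vectors = vectors / norms[:, None]
    vectors[vectors[:, 2] < 0] *= -1.0

    return DirectorField(
        vectors=vectors,
        base_positions=bases,
        layer_index=layers,
        lipid_id=lids,
        box=config.box.copy(),
    )


def tilt_angles(directors: DirectorField) -> np.ndarray:
    """Per-lipid tilt angle in degrees, measured from the z axis on [0, 90]."""
    cos_t = np.clip(np.abs(directors.vectors[:, 2]), -1.0, 1.0)
    return np.degrees(np.arccos(cos_t))


def tilt_histogram(angles: Sequence[float], bin_width: float = 1.0) -> TiltHistogram:
    """Histogram of tilt angles on [0°, 90°].

    The modal angle is the center of the maximal-count bin; ties are
    broken toward the smaller angle.  90° falls in the last bin.
    """
    if bin_width <= 0:
        raise InvalidParameterError("bin_width must be > 0")
    angles = np.asarray(angles, dtype=float)
    if len(angles) < 1:
        raise InvalidParameterError("need at least one angle")
    n_bins = int(math.ceil(90.0 / bin_width))
    edges = np.arange(n_bins + 1) * bin_width
    counts, _ = np.histogram(angles, bins=edges)
    modal = int(np.argmax(counts))  # argmax takes the first maximal bin
    return TiltHistogram(
        bin_edges=edges,
        counts=counts,
        modal_angle=float((edges[modal] + edges[modal + 1]) / 2.0),
        n_lipids=len(angles),
    )


def _bond_vectors(
    config: LipidConfiguration, include_head_bond: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """Consecutive-bead bond vectors and the lipid id of each bond.

    Beads of a lipid are taken in storage order (head first).  The
    head-to-first-tail bond is excluded by default: headgroup orientation
    is not tail order.
    """
    order = np.argsort(config.lipid_id, kind="stable")
    lid_sorted = config.lipid_id[order]
    pos_sorted = config.bead_positions[order]

    same_lipid = lid_sorted[1:] == lid_sorted[:-1]
    # position of each bead within its lipid (storage order, head first)
    is_start = np.empty(len(lid_sorted), dtype=bool)
    is_start[0] = True
    is_start[1:] = ~same_lipid
    pos_in_lipid = np.arange(len(lid_sorted)) - np.maximum.accumulate(
        np.where(is_start, np.arange(len(lid_sorted)), 0)
    )
    keep = same_lipid if include_head_bond else same_lipid & (pos_in_lipid[:-1] >= 1)

    per_lipid_bonds = np.bincount(
        np.unique(lid_sorted, return_inverse=True)[1][:-1], weights=keep
    )
    if np.any(per_lipid_bonds < 1):
        bad = np.unique(lid_sorted)[np.argmax(per_lipid_bonds < 1)]
        raise InvalidParameterError(
            f"lipid {bad} has no bond between consecutive non-head beads"
        )

    b = (pos_sorted[1:] - pos_sorted[:-1])[keep]
    if np.any(np.linalg.norm(b, axis=1) < 1e-12):
        raise DegenerateBondError("zero-length bond vector")
    return b, lid_sorted[:-1][keep]


def p2_of_vectors(vectors: np.ndarray, axis: np.ndarray | None = None) -> float:
    """P2 = mean of (3 cos²θ − 1)/2 of ``vectors`` against ``axis`` (default z)."""
    v = np.asarray(vectors, dtype=float)
    norms = np.linalg.norm(v, axis=1)
    if np.any(norms < 1e-12):
        raise DegenerateBondError("zero-length vector")
    if axis is None:
        cos_t = v[:, 2] / norms
    else:
        a = np.asarray(axis, dtype=float)
        a = a / np.linalg.norm(a)
        cos_t = (v @ a) / norms
    return float(np.mean(1.5 * cos_t**2 - 0.5))


def order_parameter_p2(
    config: LipidConfiguration,
    reference: str = "membrane_normal",
    include_head_bond: bool = False,
) -> OrderParameterResult:
    """Second-rank bond order parameter of the lipid tails.

    With ``reference="membrane_normal"`` every bond angle is measured
    against z; with ``reference="lipid_director"`` against the owning
    lipid's director, which removes the contribution of whole-molecule
    tilt and leaves pure conformational (intra-chain) disorder.
    """
    bonds, owner = _bond_vectors(config, include_head_bond=include_head_bond)
    norms = np.linalg.norm(bonds, axis=1)
    if reference == "membrane_normal":
        cos_t = bonds[:, 2] / norms
    elif reference == "lipid_director":
        field = compute_directors(config)
        axes = field.vectors[np.searchsorted(field.lipid_id, owner)]
        cos_t = np.einsum("ij,ij->i", bonds, axes) / norms
    else:
        raise InvalidParameterError(f"unknown reference {reference!r}")
    p2 = float(np.mean(1.5 * cos_t**2 - 0.5))
    # guard against rounding just past the analytic bounds
    p2 = min(1.0, max(-0.5, p2))
    return OrderParameterResult(p2=p2, reference=reference, n_bonds=len(bonds))


def interlayer_tilt_correlation(
    directors: DirectorField | Sequence[DirectorField],
    l1: int,
    l2: int,
    segments: int = 50,
    mode: str = "asymmetric",
) -> float:
    """Correlation of lipid tilt magnitudes between two layers.

    Layers are laterally divided into ``segments`` × ``segments`` bins
    (half-open, periodic in x and y, binned on lipid base positions) and
    products of scalar tilt angles are taken over all cross-layer lipid
    pairs sharing a bin, averaging over pairs, bins and frames.

    ``mode="asymmetric"`` (default) returns ⟨θ(l1)·θ(l2)⟩ / ⟨θ(l1)·θ(l1)⟩,
    normalizing by the same-layer pair average of the *first* layer (all
    ordered same-layer pairs, self-pairs included — under this reading a
    duplicated layer gives exactly 1).  ``mode="pearson"`` returns the
    symmetric Pearson correlation over the same cross-layer pairs.

    Bins where either layer is absent are skipped.
    """
    frames = [directors] if isinstance(directors, DirectorField) else list(directors)
    if segments < 1:
        raise InvalidParameterError("segments must be >= 1")

    num_sum = num_n = den_sum = den_n = 0.0
    sx = sy = sxx = syy = 0.0  # pearson accumulators

    for frame in frames:
        if frame.box is None:
            raise InvalidParameterError("DirectorField needs a box for segmentation")
        theta = tilt_angles(frame)
        for layer, name in ((l1, "l1"), (l2, "l2")):
            if not np.any(frame.layer_index == layer):
                raise InvalidParameterError(f"layer {layer} ({name}) not present")
        bx, by = float(frame.box[0]), float(frame.box[1])
        ix = np.floor(frame.base_positions[:, 0] / bx * segments).astype(int) % segments
        iy = np.floor(frame.base_positions[:, 1] / by * segments).astype(int) % segments
        seg = ix * segments + iy
        n_seg = segments * segments

        m1 = frame.layer_index == l1
        m2 = frame.layer_index == l2
        n1 = np.bincount(seg[m1], minlength=n_seg)
        n2 = np.bincount(seg[m2], minlength=n_seg)
        s1 = np.bincount(seg[m1], weights=theta[m1], minlength=n_seg)
        s2 = np.bincount(seg[m2], weights=theta[m2], minlength=n_seg)
        q1 = np.bincount(seg[m1], weights=theta[m1] ** 2, minlength=n_seg)
        q2 = np.bincount(seg[m2], weights=theta[m2] ** 2, minlength=n_seg)

        both = (n1 > 0) & (n2 > 0)  # bins with a layer absent are skipped
        num_sum += float(np.sum(s1[both] * s2[both]))
        num_n += float(np.sum(n1[both] * n2[both]))
        den_sum += float(np.sum(s1[both] ** 2))
        den_n += float(np.sum(n1[both] ** 2))
        sx += float(np.sum(n2[both] * s1[both]))
        sy += float(np.sum(n1[both] * s2[both]))
        sxx += float(np.sum(n2[both] * q1[both]))
        syy += float(np.sum(n1[both] * q2[both]))

    if num_n == 0:
        raise InvalidParameterError("no segment contains lipids of both layers")
    if mode == "asymmetric":
        den = den_sum / den_n
        if den == 0:
            raise UndefinedCorrelationError("all tilts in layer l1 are exactly zero")
        return float((num_sum / num_n) / den)
    if mode == "pearson":
        n = num_n
        ex, ey = sx / n, sy / n
        vx, vy = sxx / n - ex**2, syy / n - ey**2
        if vx <= 0 or vy <= 0:
            raise UndefinedCorrelationError("zero tilt variance within segments")
        return float((num_sum / n - ex * ey) / math.sqrt(vx * vy))
    raise InvalidParameterError(f"unknown mode {mode!r}")
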