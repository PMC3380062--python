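"""Alignment quality statistics.

Sensitivity/specificity against two-map planted truth, per-size signed
prediction-error vectors against multi-map truth, and the cumulative
aligned-feature curve (with pattern classification) used to compare
alignments qualitatively.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np

from .aligner import AlignmentResult
from .core import ContractError, IntegrityError
from .simulate import SimTruth


@dataclass(frozen=True)
class CharacteristicSet:
    """Per-size consensus counts plus cumulative aligned-feature sums.

    ``s[i]`` is the number of features in consensuses of size <= i+1
    (so ``s[-1]`` equals the total feature count N); ``s_norm = s / N``.
    """

    c: tuple[int, ...]
    s: tuple[int, ...]
    s_norm: tuple[float, ...]
    t: tuple[int, ...] | None = None


def sensitivity(result: AlignmentResult, truth: SimTruth) -> float | None:
    """Percentage of aligned (size-2) planted TSMs recovered exactly.

    A TSM counts as recovered only when some predicted size-2 consensus has
    exactly its two member features.  Returns None when the truth has no
    aligned TSMs.
    """
    aligned = truth.aligned
    if not aligned:
        return None
    predicted_pairs = {
        cons.members for cons in result.consensuses if cons.size == 2
    }
    c0 = sum(1 for t in aligned if frozenset(t.member_uids) in predicted_pairs)
    return 100.0 * c0 / len(aligned)


def specificity(result: AlignmentResult, truth: SimTruth) -> float | None:
    """Percentage of non-aligned planted TSMs left as singletons.

    Returns None when the truth has no non-aligned TSMs.
    """
    nonaligned = truth.nonaligned
    if not nonaligned:
        return None
    singleton_uids = {
        next(iter(cons.members))
        for cons in result.consensuses
        if cons.size == 1
    }
    n0 = sum(1 for t in nonaligned if t.member_uids[0] in singleton_uids)
    return 100.0 * n0 / len(nonaligned)


def prediction_errors(c, t) -> np.ndarray:
    """Signed per-size error ``c - t``: positive = false predictions,
    negative = missing hypotheses."""
    c = np.asarray(c, dtype=int)
    t = np.asarray(t, dtype=int)
    if c.shape != t.shape:
        raise ContractError(f"c and t lengths differ: {c.shape} vs {t.shape}")
    return c - t


def cam(c, n_maps: int, n_features: int) -> CharacteristicSet:
    """Cumulative aligned-feature curve over consensus sizes 1..K.

    Raises IntegrityError when the per-size counts do not conserve the
    feature total (sum of i * c_i must equal N).
    """
    c = tuple(int(x) for x in c)
    if len(c) != n_maps:
        raise ContractError(f"c must have {n_maps} entries, got {len(c)}")
    total = sum(i * ci for i, ci in enumerate(c, start=1))
    if total != n_features:
        raise IntegrityError(
            f"feature conservation violated: sum i*c_i = {total} != N = {n_features}"
        )
    s = tuple(np.cumsum([i * ci for i, ci in enumerate(c, start=1)]).tolist())
    s_norm = tuple(x / n_features for x in s) if n_features else tuple(0.0 for _ in s)
    return CharacteristicSet(c=c, s=s, s_norm=s_norm)


def classify_cam_pattern(s_norm, n_maps: int) -> str:
    """Label a normalized curve: I (all singletons), II (all full size),
    IV-H (no large consensuses), IV-L (no small consensuses), else III."""
    s_norm = tuple(s_norm)
    if len(s_norm) != n_maps:
        raise ContractError("s_norm length must equal the number of maps")
    if s_norm[0] == 1.0:
        return "I"
    if n_maps >= 2 and s_norm[n_maps - 2] == 0.0:
        return "II"
    if n_maps >= 2 and s_norm[n_maps - 1] == s_norm[n_maps - 2]:
        return "IV-H"
    if s_norm[0] == 0.0:
        return "IV-L"
    return "III"


def compare_cam(a: CharacteristicSet, b: CharacteristicSet) -> str:
    """Pointwise dominance of normalized curves (lower is better).

    Returns "first", "second", "equal" or "incomparable".
    """
    if len(a.s_norm) != len(b.s_norm):
        raise ContractError("curves must cover the same number of maps")
    av, bv = np.asarray(a.s_norm), np.asarray(b.s_norm)
    if np.array_equal(av, bv):
        return "equal"
    if np.all(av <= bv):
        return "first"
    if np.all(bv <= av):
        return "second"
    return "incomparable"


def plot_cam(
    charsets: dict[str, CharacteristicSet], path: str | os.PathLike, title: str = ""
) -> None:
    """Render one or more normalized curves (consensus size vs cumulative
    normalized feature sum) to an image file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for label, cs in charsets.items():
        sizes = range(1, len(cs.s_norm) + 1)
        ax.plot(sizes, cs.s_norm, marker="o", label=label)
    ax.set_xlabel("consensus size (number of maps)")
    ax.set_ylabel("normalized cumulative sum of aligned features")
    ax.set_ylim(-0.02, 1.02)
    if title:
        ax.set_title(title)
    if len(charsets) > 1:
        ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
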