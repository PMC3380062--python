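"""Fixed-width digit-aligned-value (DAV) encoding and string-list machinery.

Every numeric field is rendered as a zero-padded fixed-width string so that
lexicographic order of the encoded records equals numeric order of the
leading field.  Records concatenate their fields with a dollar separator;
the leading field is the sort key (mass for the primary S list, retention
time for the per-cluster R lists, which additionally carry an origin column
pointing back into the S list).  Aligned records are "whitened": the
leading field is replaced by the literal letter ``w``, which sorts after
every digit, so whitened records sink to the bottom of the list and are
never rescanned.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from decimal import ROUND_HALF_EVEN, Decimal
from typing import Iterable, Sequence

from .core import ContractError, Dataset, Feature, IntegrityError, ValidationError

SEP = "$"
WHITE = "w"


class DavOverflowError(ValueError):
    """Value does not fit the integer width of its layout."""


@dataclass(frozen=True)
class DavLayout:
    """Digit widths for one numeric field: digits before / after the point."""

    int_width: int
    dec_width: int

    def __post_init__(self) -> None:
        if self.int_width < 1 or self.dec_width < 1:
            raise ValidationError("DAV widths must be >= 1")

    @property
    def total_width(self) -> int:
        return self.int_width + 1 + self.dec_width


@dataclass(frozen=True)
class LayoutSet:
    """One layout per record field."""

    mass: DavLayout
    rt: DavLayout
    intensity: DavLayout
    map_width: int


def to_dav(x: float, int_width: int, dec_width: int) -> str:
    """Encode a non-negative number as a fixed-width zero-padded string.

    ``(1.5, 3, 4)`` gives ``"001.5000"``.  Values needing more decimals
    than ``dec_width`` are rounded half-even; values whose integer part
    exceeds ``int_width`` digits raise :class:`DavOverflowError`.
    """
    if x < 0:
        raise ValidationError(f"DAV values must be non-negative, got {x}")
    q = Decimal(repr(float(x))).quantize(
        Decimal(1).scaleb(-dec_width), rounding=ROUND_HALF_EVEN
    )
    if q >= Decimal(10) ** int_width:
        raise DavOverflowError(f"{x} does not fit in {int_width} integer digit(s)")
    width = int_width + 1 + dec_width
    return f"{q:0{width}.{dec_width}f}"


def int_to_dav(i: int, width: int) -> str:
    if i < 0:
        raise ValidationError("DAV integers must be non-negative")
    s = f"{i:0{width}d}"
    if len(s) > width:
        raise DavOverflowError(f"{i} does not fit in {width} digit(s)")
    return s


def _decimal_places(x: float, max_dec: int | None) -> int:
    exp = Decimal(repr(float(x))).normalize().as_tuple().exponent
    places = max(1, -exp)
    if max_dec is not None:
        places = min(places, max_dec)
    return places


def _int_digits(x: float) -> int:
    return len(str(int(abs(float(x)))))


def infer_field_layout(values: Iterable[float], max_dec: int | None = None) -> DavLayout:
    """Minimal layout covering every value; deterministic given the values.

    With ``max_dec=None`` the decimal width follows the values' shortest
    round-tripping decimal representation, so encoding is lossless.
    """
    vals = list(values)
    if not vals:
        raise ContractError("cannot infer a layout from no values")
    return DavLayout(
        int_width=max(_int_digits(v) for v in vals),
        dec_width=max(_decimal_places(v, max_dec) for v in vals),
    )


def infer_layout(dataset: Dataset, max_dec: int | None = None) -> LayoutSet:
    """Infer per-field layouts for a dataset (mass, rt, intensity, map index)."""
    if dataset.n_features == 0:
        raise ContractError("cannot infer layouts for an empty dataset")
    feats = dataset.features
    return LayoutSet(
        mass=infer_field_layout((f.mz for f in feats), max_dec),
        rt=infer_field_layout((f.rt for f in feats), max_dec),
        intensity=infer_field_layout((f.intensity for f in feats), max_dec),
        map_width=len(str(dataset.n_maps)),
    )


def encode(
    feature: Feature,
    layouts: LayoutSet,
    leading: str = "mass",
    origin: int | None = None,
    origin_width: int = 0,
) -> str:
    """Encode a feature as a record string.

    ``leading="mass"`` produces the S-list form ``m$r$w$z``;
    ``leading="rt"`` produces the R-list form ``r$m$w$z$o`` and requires
    ``origin`` (the record's index in the S list) and ``origin_width``.
    """
    m = to_dav(feature.mz, layouts.mass.int_width, layouts.mass.dec_width)
    r = to_dav(feature.rt, layouts.rt.int_width, layouts.rt.dec_width)
    w = int_to_dav(feature.map_index, layouts.map_width)
    z = to_dav(feature.intensity, layouts.intensity.int_width, layouts.intensity.dec_width)
    if leading == "mass":
        return SEP.join((m, r, w, z))
    if leading == "rt":
        if origin is None or origin_width < 1:
            raise ContractError("rt-leading records require origin and origin_width")
        return SEP.join((r, m, w, z, int_to_dav(origin, origin_width)))
    raise ContractError(f"unknown leading field {leading!r}")


def decode(record: str, leading: str = "mass") -> dict[str, float | int | None]:
    """Decode a record back to numeric fields.

    Whitened records decode with the leading field set to ``None``.
    """
    parts = record.split(SEP)
    out: dict[str, float | int | None] = {"origin": None}
    if leading == "mass":
        if len(parts) != 4:
            raise ContractError(f"malformed mass-leading record {record!r}")
        m, r, w, z = parts
        out["mz"] = None if m == WHITE else float(m)
        out["rt"] = float(r)
    elif leading == "rt":
        if len(parts) != 5:
            raise ContractError(f"malformed rt-leading record {record!r}")
        r, m, w, z, o = parts
        out["rt"] = None if r == WHITE else float(r)
        out["mz"] = float(m)
        out["origin"] = int(o)
    else:
        raise ContractError(f"unknown leading field {leading!r}")
    out["map_index"] = int(w)
    out["intensity"] = float(z)
    return out


def is_whitened(record: str) -> bool:
    return record.startswith(WHITE + SEP)


@dataclass(frozen=True)
class StringList:
    """An ordered list of encoded records plus side metadata.

    ``uids[i]`` is the dataset uid of record ``i`` (S lists only; R lists
    trace identity through their origin field instead).
    """

    records: tuple[str, ...]
    leading: str
    layouts: LayoutSet
    uids: tuple[int, ...] | None = None

    def __len__(self) -> int:
        return len(self.records)

    def n_active(self) -> int:
        """Number of un-whitened records (assumes whitened ones are at the end)."""
        n = len(self.records)
        while n > 0 and is_whitened(self.records[n - 1]):
            n -= 1
        return n


def from_features(
    features: Sequence[Feature], layouts: LayoutSet, leading: str = "mass"
) -> StringList:
    """Build an S-type string list from features (record order = input order)."""
    records = tuple(encode(f, layouts, leading=leading) for f in features)
    return StringList(
        records=records,
        leading=leading,
        layouts=layouts,
        uids=tuple(f.uid for f in features),
    )


def sort_strings(sl: StringList) -> StringList:
    """Lexicographically sort the records (stable: ties keep input order).

    For un-whitened records this equals ascending numeric order of the
    leading value; whitened records sort after all un-whitened ones because
    ``w`` follows every digit in ASCII.
    """
    order = sorted(range(len(sl.records)), key=lambda i: sl.records[i])
    records = tuple(sl.records[i] for i in order)
    uids = tuple(sl.uids[i] for i in order) if sl.uids is not None else None
    return replace(sl, records=records, uids=uids)


def whiten(sl: StringList, positions: Iterable[int]) -> StringList:
    """Replace the leading field of the named records by the letter ``w``."""
    records = list(sl.records)
    for p in positions:
        rec = records[p]
        if is_whitened(rec):
            raise IntegrityError(f"record at position {p} is already whitened")
        records[p] = WHITE + rec[rec.index(SEP):]
    return replace(sl, records=tuple(records))
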