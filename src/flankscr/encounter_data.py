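"""Encounter histories for two-mark (bilateral) capture-recapture data.

Encounter codes per individual x trap x occasion:

==== =====================================================================
code meaning
==== =====================================================================
0    no detection
1    type-1 mark only (convention: left flank)
2    type-2 mark only (convention: right flank)
3    both marks, non-simultaneous (identity of the pairing not observed)
4    both marks photographed simultaneously (identity-resolving)
==== =====================================================================

The *latent* data are the true histories of the ``n`` unique individuals
detected at least once.  The *observed* data are what the camera survey
yields: fully identified histories (``known``), plus single left-flank
and single right-flank histories that may or may not belong to the same
animal.  The deterministic map from latent to observed histories, and
the feasibility of a candidate left-right matching, are defined here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

# Mark-type convention (the model is symmetric in the two marks).
LEFT_CODE = 1
RIGHT_CODE = 2
BOTH_CODE = 3
SIMUL_CODE = 4

VALID_CODES = frozenset({0, 1, 2, 3, 4})


@dataclass
class TrapArray:
    """Trap locations, covariates and the operation matrix ``m[j, t]``."""

    ids: list[str]
    xy: np.ndarray           # (J, 2) planar coordinates, meters
    elevation: np.ndarray    # (J,) meters
    operation: np.ndarray    # (J, T) binary

    def __post_init__(self) -> None:
        self.xy = np.asarray(self.xy, dtype=float)
        self.elevation = np.asarray(self.elevation, dtype=float)
        self.operation = np.asarray(self.operation, dtype=np.int8)
        J = len(self.ids)
        if len(set(self.ids)) != J:
            raise ValueError("duplicate trap ids")
        if self.xy.shape != (J, 2) or not np.all(np.isfinite(self.xy)):
            raise ValueError("trap coordinates must be a finite (J, 2) array")
        if self.elevation.shape != (J,):
            raise ValueError("elevation must have one entry per trap")
        if self.operation.ndim != 2 or self.operation.shape[0] != J:
            raise ValueError("operation matrix must be (J, T)")
        if self.operation.shape[1] < 1:
            raise ValueError("need at least one occasion")
        if not np.isin(self.operation, (0, 1)).all():
            raise ValueError("operation entries must be 0/1")

    @property
    def n_traps(self) -> int:
        return len(self.ids)

    @property
    def n_occasions(self) -> int:
        return self.operation.shape[1]

    def index_of(self, trap_id: str) -> int:
        try:
            return self.ids.index(trap_id)
        except ValueError:
            raise KeyError(f"unknown trap id: {trap_id!r}") from None


@dataclass
class LatentHistory:
    """One individual's true encounter history on the J x T lattice."""

    events: np.ndarray  # (J, T) codes 0..4

    def __post_init__(self) -> None:
        self.events = np.asarray(self.events, dtype=np.int8)
        if self.events.ndim != 2:
            raise ValueError("events must be a (J, T) array")
        bad = set(np.unique(self.events)) - VALID_CODES
        if bad:
            raise ValueError(f"invalid encounter codes: {sorted(bad)}")

    def validate_operation(self, traps: TrapArray) -> None:
        if np.any((self.events > 0) & (traps.operation == 0)):
            raise ValueError("encounter recorded at a non-operational trap-occasion")


def _check_side(histories: list[np.ndarray], allowed: set[int], side: str) -> None:
    for h in histories:
        codes = set(np.unique(h)) - {0}
        if not codes:
            raise ValueError(f"{side} history with no events")
        if codes - allowed:
            raise ValueError(f"{side} history contains codes {sorted(codes - allowed)}")


@dataclass
class ObservedEncounterData:
    """Observed two-mark data: known histories plus unlinked single flanks.

    ``known`` histories carry codes 0-4 and certain identity; ``left``
    histories carry only codes {0, 1}; ``right`` only {0, 2}.  Record
    order is stable (file order) and indices into the three lists are
    the record handles used throughout the package.
    """

    known: list[np.ndarray] = field(default_factory=list)
    left: list[np.ndarray] = field(default_factory=list)
    right: list[np.ndarray] = field(default_factory=list)
    known_ids: list[str] | None = None
    left_ids: list[str] | None = None
    right_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.known = [np.asarray(h, dtype=np.int8) for h in self.known]
        self.left = [np.asarray(h, dtype=np.int8) for h in self.left]
        self.right = [np.asarray(h, dtype=np.int8) for h in self.right]
        shapes = {h.shape for h in self.known + self.left + self.right}
        if len(shapes) > 1:
            raise ValueError("all histories must share the same (J, T) lattice")
        for h in self.known:
            if not (h > 0).any():
                raise ValueError("known history with no events")
        _check_side(self.left, {LEFT_CODE}, "left")
        _check_side(self.right, {RIGHT_CODE}, "right")
        if self.known_ids is None:
            self.known_ids = [f"K{i+1}" for i in range(len(self.known))]
        if self.left_ids is None:
            self.left_ids = [f"L{i+1}" for i in range(len(self.left))]
        if self.right_ids is None:
            self.right_ids = [f"R{i+1}" for i in range(len(self.right))]

    @property
    def n_known(self) -> int:
        return len(self.known)

    @property
    def n1(self) -> int:
        """Number of single type-1 (left-flank) records."""
        return len(self.left)

    @property
    def n2(self) -> int:
        """Number of single type-2 (right-flank) records."""
        return len(self.right)

    @property
    def n_records(self) -> int:
        """Total observed records n-tilde = n_known + n1 + n2."""
        return self.n_known + self.n1 + self.n2

    @property
    def shape(self) -> tuple[int, int]:
        for h in self.known + self.left + self.right:
            return h.shape
        raise ValueError("no records")


@dataclass
class MatchState:
    """A partial bipartite matching between left and right single records.

    ``pairs`` holds (left-index, right-index) links.  Under a link the
    left record carries the merged history and z = 1; the right record
    becomes a ghost (z = 0).  Known records always have z = 1.  The
    number of unique detected individuals is
    ``n = n_known + #unmatched-left + #unmatched-right + #pairs``.
    """

    pairs: list[tuple[int, int]] = field(default_factory=list)

    def validate(self, data: ObservedEncounterData) -> None:
        lefts = [l for l, _ in self.pairs]
        rights = [r for _, r in self.pairs]
        if len(set(lefts)) != len(lefts) or len(set(rights)) != len(rights):
            raise ValueError("a record may appear in at most one link")
        if any(l < 0 or l >= data.n1 for l in lefts):
            raise ValueError("left index out of range")
        if any(r < 0 or r >= data.n2 for r in rights):
            raise ValueError("right index out of range")

    def z_flags(self, data: ObservedEncounterData) -> np.ndarray:
        """z per record, ordered known then left then right."""
        z = np.ones(data.n_records, dtype=np.int8)
        ghost_rights = {r for _, r in self.pairs}
        for r in ghost_rights:
            z[data.n_known + data.n1 + r] = 0
        return z

    def n_individuals(self, data: ObservedEncounterData) -> int:
        return data.n_records - len(self.pairs)


# ---------------------------------------------------------------------------
# Occasion construction

_CODE_PRIORITY = (SIMUL_CODE, BOTH_CODE)  # strongest codes kept on collapse


def _combine_codes(codes: set[int]) -> int:
    """Collapse multiple within-occasion codes at one trap to a single code.

    Simultaneity (4) dominates; otherwise evidence of both flanks (code 3,
    or codes 1 and 2 together) gives 3; otherwise the single-flank code.
    """
    codes = codes - {0}
    if SIMUL_CODE in codes:
        return SIMUL_CODE
    if BOTH_CODE in codes or {LEFT_CODE, RIGHT_CODE} <= codes:
        return BOTH_CODE
    if codes == {LEFT_CODE}:
        return LEFT_CODE
    if codes == {RIGHT_CODE}:
        return RIGHT_CODE
    raise ValueError(f"cannot combine codes {sorted(codes)}")


def collapse_to_occasions(
    raw_records: pd.DataFrame,
    occasion_length: int,
    n_days: int | None = None,
) -> pd.DataFrame:
    """Collapse day-indexed detections into sampling occasions.

    Occasion = ceil(day / occasion_length) with 1-based days.  Within a
    record x trap x occasion cell, repeated detections collapse to one
    event keeping the strongest code (4 > 3 > 1/2; codes 1 and 2 seen
    in the same cell combine to 3).

    Parameters
    ----------
    raw_records
        Columns ``record_id, kind, trap_id, day, code``.
    occasion_length
        Days per occasion (>= 1).
    n_days
        Survey length; days beyond it are rejected.
    """
    if occasion_length < 1:
        raise ValueError("occasion_length must be >= 1")
    required = {"record_id", "kind", "trap_id", "day", "code"}
    missing = required - set(raw_records.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    days = raw_records["day"].to_numpy()
    if (days < 1).any():
        raise ValueError("day indices must be >= 1")
    if n_days is not None and (days > n_days).any():
        bad = int(days.max())
        raise ValueError(f"day {bad} exceeds the survey length of {n_days} days")
    df = raw_records.copy()
    df["occasion"] = -(-df["day"] // occasion_length)  # ceil division
    rows = []
    for (rid, kind, tid, occ), grp in df.groupby(
        ["record_id", "kind", "trap_id", "occasion"], sort=True
    ):
        code = _combine_codes(set(grp["code"]))
        rows.append({"record_id": rid, "kind": kind, "trap_id": tid,
                     "occasion": int(occ), "code": code})
    return pd.DataFrame(rows, columns=["record_id", "kind", "trap_id", "occasion", "code"])


# ---------------------------------------------------------------------------
# Latent <-> observed maps

def merge_pair(left: np.ndarray, right: np.ndarray) -> np.ndarray:
    """Merge a left-only and a right-only history into one latent history.

    Cellwise: (0,0)->0, (1,0)->1, (0,2)->2, (1,2)->3.  Simultaneity (4)
    can never be produced by merging: it is only directly observed.
    """
    left = np.asarray(left, dtype=np.int8)
    right = np.asarray(right, dtype=np.int8)
    if left.shape != right.shape:
        raise ValueError("histories defined on different lattices")
    if not np.isin(left, (0, LEFT_CODE)).all():
        raise ValueError("left history may only contain codes {0, 1}")
    if not np.isin(right, (0, RIGHT_CODE)).all():
        raise ValueError("right history may only contain codes {0, 2}")
    return (left + right).astype(np.int8)  # 1 + 2 = 3 exactly where both occur


def split_history(latent: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Project a latent history onto its left and right observable parts."""
    latent = np.asarray(latent)
    left = np.where(np.isin(latent, (LEFT_CODE, BOTH_CODE)), LEFT_CODE, 0)
    right = np.where(np.isin(latent, (RIGHT_CODE, BOTH_CODE)), RIGHT_CODE, 0)
    return left.astype(np.int8), right.astype(np.int8)


def latent_to_observed(latent_histories: list[np.ndarray]) -> ObservedEncounterData:
    """Spawn the observed data from a set of true (latent) histories.

    An individual with at least one simultaneous (code-4) event is fully
    identified and emits one known record with its codes intact.  An
    individual never photographed simultaneously emits an unlinked left
    record and/or an unlinked right record.  All-zero histories emit
    nothing (an undetected animal leaves no record).
    """
    known, left, right = [], [], []
    for h in latent_histories:
        h = np.asarray(h, dtype=np.int8)
        if not (h > 0).any():
            continue
        if (h == SIMUL_CODE).any():
            known.append(h.copy())
        else:
            l, r = split_history(h)
            if (l > 0).any():
                left.append(l)
            if (r > 0).any():
                right.append(r)
    return ObservedEncounterData(known=known, left=left, right=right)


def is_feasible(match: MatchState, observed: ObservedEncounterData) -> bool:
    """Could the observed data have been spawned under this matching?

    Reconstructs latent histories implied by the matching (known records
    untouched; linked pairs merged; singles kept) and re-applies
    :func:`latent_to_observed`; feasible iff the observed left/right
    records are reproduced exactly with every record used exactly once.
    """
    try:
        match.validate(observed)
    except ValueError:
        return False
    matched_left = {l for l, _ in match.pairs}
    matched_right = {r for _, r in match.pairs}
    latent: list[np.ndarray] = []
    for l, r in match.pairs:
        latent.append(merge_pair(observed.left[l], observed.right[r]))
    latent += [observed.left[i] for i in range(observed.n1) if i not in matched_left]
    latent += [observed.right[i] for i in range(observed.n2) if i not in matched_right]
    spawned = latent_to_observed(latent)
    if spawned.n_known:
        return False  # merging can never create identity-resolving records
    key = lambda hists: sorted(h.tobytes() for h in hists)
    return (key(spawned.left) == key(observed.left)
            and key(spawned.right) == key(observed.right))


def single_side_observed(data: ObservedEncounterData,
                         side: str = "right") -> ObservedEncounterData:
    """Conventional one-sided dataset for a single-mark analysis.

    Projects every known individual's history onto one flank and keeps
    that side's single records; each resulting history is treated as an
    identified individual (the classical analysis that discards the
    other flank).  Individuals with no detection on the chosen side
    drop out.
    """
    if side == "right":
        codes, out, singles = (RIGHT_CODE, BOTH_CODE, SIMUL_CODE), RIGHT_CODE, data.right
    elif side == "left":
        codes, out, singles = (LEFT_CODE, BOTH_CODE, SIMUL_CODE), LEFT_CODE, data.left
    else:
        raise ValueError("side must be 'left' or 'right'")
    hists = []
    for h in list(data.known) + list(singles):
        proj = np.where(np.isin(h, codes), out, 0).astype(np.int8)
        if proj.any():
            hists.append(proj)
    return ObservedEncounterData(known=hists)


# ---------------------------------------------------------------------------
# File I/O

def write_traps(traps: TrapArray, path) -> None:
    T = traps.n_occasions
    df = pd.DataFrame({"trap_id": traps.ids,
                       "x": traps.xy[:, 0], "y": traps.xy[:, 1],
                       "elevation": traps.elevation})
    for t in range(T):
        df[f"op_{t+1}"] = traps.operation[:, t]
    df.to_csv(path, index=False)


def read_traps(path) -> TrapArray:
    df = pd.read_csv(path)
    required = {"trap_id", "x", "y", "elevation"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"traps file missing columns: {sorted(missing)}")
    op_cols = sorted((c for c in df.columns if c.startswith("op_")),
                     key=lambda c: int(c.split("_")[1]))
    if not op_cols:
        raise ValueError("traps file has no op_<t> occasion columns")
    return TrapArray(ids=[str(v) for v in df["trap_id"]],
                     xy=df[["x", "y"]].to_numpy(float),
                     elevation=df["elevation"].to_numpy(float),
                     operation=df[op_cols].to_numpy())


def write_detections(detections: pd.DataFrame, path) -> None:
    cols = ["record_id", "kind", "trap_id", "occasion", "code"]
    missing = set(cols) - set(detections.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    detections[cols].to_csv(path, index=False)


def read_detections(path, traps: TrapArray) -> ObservedEncounterData:
    """Assemble observed histories from an occasion-level detections table."""
    df = pd.read_csv(path)
    return detections_to_observed(df, traps)


def detections_to_observed(df: pd.DataFrame, traps: TrapArray) -> ObservedEncounterData:
    required = {"record_id", "kind", "trap_id", "occasion", "code"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"detections missing columns: {sorted(missing)}")
    J, T = traps.n_traps, traps.n_occasions
    side_allowed = {"known": VALID_CODES - {0},
                    "left": {LEFT_CODE}, "right": {RIGHT_CODE}}
    hists: dict[str, dict[str, np.ndarray]] = {"known": {}, "left": {}, "right": {}}
    order: dict[str, list[str]] = {"known": [], "left": [], "right": []}
    for row in df.itertuples(index=False):
        kind = str(row.kind)
        if kind not in side_allowed:
            raise ValueError(f"unknown record kind: {kind!r}")
        code = int(row.code)
        if code not in side_allowed[kind]:
            raise ValueError(f"code {code} not allowed for kind {kind!r}")
        j = traps.index_of(str(row.trap_id))
        t = int(row.occasion) - 1
        if not 0 <= t < T:
            raise ValueError(f"occasion {row.occasion} outside 1..{T}")
        rid = str(row.record_id)
        if rid not in hists[kind]:
            hists[kind][rid] = np.zeros((J, T), dtype=np.int8)
            order[kind].append(rid)
        hists[kind][rid][j, t] = max(hists[kind][rid][j, t], code)
    return ObservedEncounterData(
        known=[hists["known"][r] for r in order["known"]],
        left=[hists["left"][r] for r in order["left"]],
        right=[hists["right"][r] for r in order["right"]],
        known_ids=order["known"], left_ids=order["left"], right_ids=order["right"],
    )


def observed_to_detections(data: ObservedEncounterData, traps: TrapArray) -> pd.DataFrame:
    """Inverse of :func:`detections_to_observed` (lossless round-trip)."""
    rows = []
    for kind, hists, ids in (("known", data.known, data.known_ids),
                             ("left", data.left, data.left_ids),
                             ("right", data.right, data.right_ids)):
        for rid, h in zip(ids, hists):
            for j, t in zip(*np.nonzero(h)):
                rows.append({"record_id": rid, "kind": kind,
                             "trap_id": traps.ids[j], "occasion": t + 1,
                             "code": int(h[j, t])})
    return pd.DataFrame(rows, columns=["record_id", "kind", "trap_id", "occasion", "code"])


def write_history_matrix(data: ObservedEncounterData, traps: TrapArray, path) -> None:
    """Export observed histories as n-tilde rows x (J*T) code columns.

    Column order is trap-major: all occasions of trap 1, then trap 2, ...
    """
    J, T = data.shape
    cols = [f"{traps.ids[j]}_t{t+1}" for j in range(J) for t in range(T)]
    rows, rids, kinds = [], [], []
    for kind, hists, ids in (("known", data.known, data.known_ids),
                             ("left", data.left, data.left_ids),
                             ("right", data.right, data.right_ids)):
        for rid, h in zip(ids, hists):
            rows.append(h.reshape(-1))  # row-major (J, T) == trap-major
            rids.append(rid)
            kinds.append(kind)
    df = pd.DataFrame(rows, columns=cols)
    df.insert(0, "kind", kinds)
    df.insert(0, "record_id", rids)
    df.to_csv(path, index=False)


def read_history_matrix(path, traps: TrapArray) -> ObservedEncounterData:
    df = pd.read_csv(path)
    if "record_id" not in df.columns or "kind" not in df.columns:
        raise ValueError("history matrix needs record_id and kind columns")
    J, T = traps.n_traps, traps.n_occasions
    code_cols = [c for c in df.columns if c not in ("record_id", "kind")]
    if len(code_cols) != J * T:
        raise ValueError(f"expected {J * T} code columns, found {len(code_cols)}")
    codes = df[code_cols].to_numpy()
    if not np.isin(codes, sorted(VALID_CODES)).all():
        raise ValueError("history matrix contains codes outside 0..4")
    known, left, right = [], [], []
    kid, lid, rid = [], [], []
    for i, kind in enumerate(df["kind"]):
        h = codes[i].reshape(J, T).astype(np.int8)
        rec = str(df["record_id"].iloc[i])
        if kind == "known":
            known.append(h); kid.append(rec)
        elif kind == "left":
            left.append(h); lid.append(rec)
        elif kind == "right":
            right.append(h); rid.append(rec)
        else:
            raise ValueError(f"unknown record kind: {kind!r}")
    return ObservedEncounterData(known=known, left=left, right=right,
                                 known_ids=kid, left_ids=lid, right_ids=rid)
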