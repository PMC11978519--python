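"""Grouping pairwise match probabilities into persistent unit identities.

All pairs of units across all sessions are sorted by match probability
(descending, ties broken lexicographically by session/unit ids) and
visited serially; a pair with probability above 0.5 proposes merging the
two units' current groups.  Three rules decide whether the merge happens:

* liberal — always;
* default — each unit of the pair must have probability > 0.5 with every
  unit of the other group lying in the same or an immediately adjacent
  recording (by session order);
* conservative — every cross-group unit pair must have probability > 0.5.

A merge that would put two units of one session into one group is always
skipped, in every mode, so a global id appears at most once per session.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

MODES = ("liberal", "default", "conservative")


class _DisjointSet:
    """Union-find over unit indices, tracking members per group."""

    def __init__(self, n: int):
        self.parent = list(range(n))
        self.members = {i: [i] for i in range(n)}

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return
        if len(self.members[ra]) < len(self.members[rb]):
            ra, rb = rb, ra
        self.parent[rb] = ra
        self.members[ra].extend(self.members.pop(rb))


def assign_global_ids(
    posteriors: np.ndarray,
    unit_ids: np.ndarray,
    session_ids: np.ndarray,
    session_order: list[int] | None = None,
    mode: str = "default",
    cutoff: float = 0.5,
) -> pd.DataFrame:
    """Assign one persistent global id per tracked neuron.

    Parameters
    ----------
    posteriors : (n, n) symmetric match-probability matrix.
    unit_ids, session_ids : per-row identifiers.
    session_order : session ids in recording order (adjacency is order
        index +/- 1); defaults to sorted distinct session ids.
    mode : 'liberal', 'default' or 'conservative'.

    Returns
    -------
    DataFrame with columns unit_id, session_id, global_id, mode, in the
    input unit order.  Global ids are renumbered by first appearance
    (session order, then unit id).
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
    unit_ids = np.asarray(unit_ids)
    session_ids = np.asarray(session_ids)
    n = unit_ids.size
    if session_order is None:
        session_order = sorted(set(session_ids.tolist()))
    order_of = {s: k for k, s in enumerate(session_order)}
    rank = np.array([order_of[s] for s in session_ids])

    p = np.asarray(posteriors, dtype=float)
    pairs = [
        (i, j)
        for i in range(n)
        for j in range(i + 1, n)
        if p[i, j] > cutoff and session_ids[i] != session_ids[j]
    ]
    pairs.sort(
        key=lambda ij: (
            -p[ij[0], ij[1]],
            session_ids[ij[0]], unit_ids[ij[0]],
            session_ids[ij[1]], unit_ids[ij[1]],
        )
    )

    dsu = _DisjointSet(n)
    for i, j in pairs:
        ri, rj = dsu.find(i), dsu.find(j)
        if ri == rj:
            continue
        group_i, group_j = dsu.members[ri], dsu.members[rj]
        sessions_i = {session_ids[m] for m in group_i}
        sessions_j = {session_ids[m] for m in group_j}
        if sessions_i & sessions_j:
            continue  # session-uniqueness: never two units of one session
        if _merge_allowed(mode, i, j, group_i, group_j, p, rank, cutoff):
            dsu.union(ri, rj)

    roots = [dsu.find(i) for i in range(n)]
    first_key = {}
    for i in range(n):
        key = (rank[i], unit_ids[i])
        r = roots[i]
        if r not in first_key or key < first_key[r]:
            first_key[r] = key
    ordered_roots = sorted(set(roots), key=lambda r: first_key[r])
    gid_of = {r: g for g, r in enumerate(ordered_roots)}
    return pd.DataFrame(
        {
            "unit_id": unit_ids,
            "session_id": session_ids,
            "global_id": [gid_of[r] for r in roots],
            "mode": mode,
        }
    )


def _merge_allowed(mode, i, j, group_i, group_j, p, rank, cutoff) -> bool:
    if mode == "liberal":
        return True
    if mode == "conservative":
        return all(
            p[a, b] > cutoff for a in group_i for b in group_j
        )
    # default: each unit of the pair must match every unit of the other
    # group in the same or an immediately adjacent recording
    for u, other in ((i, group_j), (j, group_i)):
        for w in other:
            if abs(rank[w] - rank[u]) <= 1 and not p[u, w] > cutoff:
                return False
    return True


def within_session_match_report(
    posteriors: np.ndarray,
    unit_ids: np.ndarray,
    session_ids: np.ndarray,
    cutoff: float = 0.5,
) -> pd.DataFrame:
    """Within-session unit pairs with P > cutoff: potential oversplits.

    These pairs are reported for curation but never merged by the
    tracking algorithms.
    """
    unit_ids = np.asarray(unit_ids)
    session_ids = np.asarray(session_ids)
    rows = []
    n = unit_ids.size
    for i in range(n):
        for j in range(i + 1, n):
            if session_ids[i] == session_ids[j] and posteriors[i, j] > cutoff:
                rows.append(
                    {
                        "session_id": session_ids[i],
                        "unit_i": unit_ids[i],
                        "unit_j": unit_ids[j],
                        "match_probability": posteriors[i, j],
                    }
                )
    return pd.DataFrame(
        rows, columns=["session_id", "unit_i", "unit_j", "match_probability"]
    )


def presence_matrix(
    tracks: pd.DataFrame, session_order: list[int] | None = None
) -> pd.DataFrame:
    """Binary global_id x session presence matrix, sorted by first appearance.

    A neuron may be absent on some sessions and reappear later; gaps are
    simply zeros in its row.
    """
    if session_order is None:
        session_order = sorted(tracks["session_id"].unique().tolist())
    rank = {s: k for k, s in enumerate(session_order)}
    mat = pd.DataFrame(
        0,
        index=sorted(tracks["global_id"].unique()),
        columns=session_order,
        dtype=int,
    )
    for row in tracks.itertuples(index=False):
        mat.loc[row.global_id, row.session_id] = 1
    first = mat.apply(
        lambda r: min(rank[s] for s in session_order if r[s]), axis=1
    )
    mat = mat.loc[first.sort_values(kind="stable").index]
    mat.index.name = "global_id"
    return mat


def track_probability_curve(
    tracks: pd.DataFrame,
    day_offsets: dict[int, int],
) -> pd.DataFrame:
    """P(track) as a function of the signed day gap between recordings.

    For each ordered session pair, the fraction of the reference
    session's units whose global id also appears in the other session;
    positive day gaps look into the reference session's future, negative
    into its past.  Fractions are averaged within each signed day-gap bin.
    """
    sessions = sorted(day_offsets, key=lambda s: day_offsets[s])
    by_session = {
        s: set(tracks.loc[tracks["session_id"] == s, "global_id"]) for s in sessions
    }
    rows = []
    for ref in sessions:
        for other in sessions:
            if ref == other:
                continue
            n_ref = len(by_session[ref])
            if n_ref == 0:
                continue
            tracked = len(by_session[ref] & by_session[other])
            rows.append(
                {
                    "delta_days": day_offsets[other] - day_offsets[ref],
                    "fraction": tracked / n_ref,
                }
            )
    df = pd.DataFrame(rows, columns=["delta_days", "fraction"])
    if df.empty:
        return pd.DataFrame(columns=["delta_days", "p_track", "n_pairs"])
    out = (
        df.groupby("delta_days")["fraction"]
        .agg(p_track="mean", n_pairs="size")
        .reset_index()
    )
    return out
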