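"""Recurrent differential events per group and shared/unique set logic.

A differential event is *recurrent* within a group (histology or splicing
cluster) when it is called in at least ``min_n`` samples of that group
(default 2).  Its direction is ``inclusion_gain`` or ``skipping`` when all
supporting samples agree, ``mixed`` otherwise.  The decomposition into
group-specific versus shared events follows exact set-intersection
(UpSet) semantics.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping

import numpy as np
import pandas as pd


@dataclass
class RecurrentEventSet:
    group: str
    splice_type: str
    #: event_id -> (direction, n_samples_supporting)
    events: pd.DataFrame  # index event_id; columns direction, n_samples

    @property
    def event_ids(self) -> frozenset:
        return frozenset(self.events.index)


def recurrent_events(
    calls: pd.DataFrame,
    groups: Mapping[str, str] | pd.Series,
    min_n: int = 2,
    splice_type: str = "SE",
) -> list[RecurrentEventSet]:
    """Per group, events called in >= ``min_n`` samples, with direction."""
    groups = pd.Series(dict(groups) if not isinstance(groups, pd.Series) else groups)
    unknown = set(groups.index) - set(calls.columns)
    if unknown:
        raise ValueError(f"samples in groups but not in call matrix: {sorted(unknown)[:5]}")

    out = []
    for group in sorted(groups.unique()):
        samples = groups.index[groups == group]
        sub = calls[samples].to_numpy(dtype=float)
        called = np.abs(np.nan_to_num(sub)) > 0
        n_sup = called.sum(axis=1)
        keep = n_sup >= min_n
        gains = ((np.nan_to_num(sub) > 0) & called).sum(axis=1)
        losses = ((np.nan_to_num(sub) < 0) & called).sum(axis=1)
        direction = np.where(
            (gains > 0) & (losses > 0), "mixed",
            np.where(gains > 0, "inclusion_gain", "skipping"),
        )
        events = pd.DataFrame(
            {"direction": direction[keep], "n_samples": n_sup[keep]},
            index=calls.index[keep],
        )
        out.append(RecurrentEventSet(group=str(group), splice_type=splice_type,
                                     events=events))
    return out


def group_set_decomposition(sets: list[RecurrentEventSet]):
    """UpSet-style decomposition of group event sets.

    Returns ``(membership, pattern_counts, unique_counts)``:

    - membership: event x group boolean DataFrame over the union;
    - pattern_counts: one row per non-empty group combination with the
      number of events belonging to exactly that combination;
    - unique_counts: events per group found in no other group.
    """
    if len(sets) < 2:
        raise ValueError("need at least two groups to decompose")
    names = [s.group for s in sets]
    if len(set(names)) != len(names):
        raise ValueError("duplicate group names")
    union = sorted(set().union(*(s.event_ids for s in sets)))
    membership = pd.DataFrame(
        {s.group: [e in s.event_ids for e in union] for s in sets},
        index=pd.Index(union, name="event_id"),
    )

    rows = []
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            in_combo = membership[list(combo)].all(axis=1)
            out_combo = ~membership[[g for g in names if g not in combo]].any(axis=1) \
                if len(combo) < len(names) else pd.Series(True, index=membership.index)
            rows.append({
                "groups": "&".join(combo),
                "degree": r,
                "n_events": int((in_combo & out_combo).sum()),
            })
    pattern_counts = pd.DataFrame(rows)

    unique_counts = {
        g: int((membership[g] & (membership.sum(axis=1) == 1)).sum()) for g in names
    }
    return membership, pattern_counts, pd.Series(unique_counts, name="n_unique")


def per_patient_normalized_counts(
    sets: list[RecurrentEventSet],
    n_patients: Mapping[str, int],
) -> pd.DataFrame:
    """Group-unique recurrent events per patient, reverse-ordered by unique count."""
    _, _, unique_counts = group_set_decomposition(sets)
    rows = []
    for group, n_unique in unique_counts.items():
        n = int(n_patients[group])
        if n <= 0:
            raise ValueError(f"group {group!r} has no patients")
        rows.append({
            "group": group,
            "n_unique": n_unique,
            "n_patients": n,
            "unique_per_patient": round(n_unique / n, 6),
        })
    out = pd.DataFrame(rows).sort_values(
        ["n_unique", "group"], ascending=[False, True]
    ).reset_index(drop=True)
    return out
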