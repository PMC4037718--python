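"""Ligand-based virtual screening in the fragrance-like chemical space.

The protocol: curate fragrance families (drop promiscuous molecules listed
in many families, keep fragrance-like members only, optionally cap the
heavy-atom count, require a minimum family size); pick a per-space
*medoid* reference — the member with the lowest summed city-block distance
to all other members; dilute the remaining actives in a background
database; rank every candidate by city-block distance to the reference;
and score the ranking with a ROC curve, its AUC (in percent, ties counted
half, i.e. the Mann-Whitney probability that an active outranks a decoy)
and the recovery of actives at fixed screened fractions of the database
(0.1%, 1% and 10% by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from . import fl_filter as _fl
from .fingerprints import DescriptorSpace, get_space
from .molio import MoleculeRecord, records_from_smiles_list

DEFAULT_FRACTIONS = (0.001, 0.01, 0.1)


@dataclass
class FragranceFamily:
    """A named fragrance molecule family after curation."""

    name: str
    members: list[MoleculeRecord]
    n_raw: int = 0
    n_removed_promiscuous: int = 0
    n_removed_non_fl: int = 0
    n_removed_hac_cap: int = 0

    def __len__(self) -> int:
        return len(self.members)

    @property
    def mean_hac(self) -> float:
        return float(np.mean([r.hac for r in self.members]))


def curate_families(
    raw: Mapping[str, Sequence[str]],
    min_size: int = 10,
    max_membership: int = 5,
    hac_cap: int | None = None,
) -> list[FragranceFamily]:
    """Apply the family curation rules to raw ``{name: [SMILES, ...]}`` input.

    In order: (1) molecules listed in more than ``max_membership`` families
    are removed from all of them (promiscuous smells carry no family
    signal); (2) non-fragrance-like molecules are removed; (3) optionally,
    members above ``hac_cap`` heavy atoms are removed; (4) families left
    with fewer than ``min_size`` members are dropped.  Family and member
    order follow the input; duplicates within a family collapse to one.
    """
    parsed: dict[str, list[MoleculeRecord]] = {}
    for name, smiles_list in raw.items():
        records = records_from_smiles_list(
            smiles_list, ids=[f"{name}:{i + 1:03d}" for i in range(len(smiles_list))]
        )
        seen: set[str] = set()
        unique = []
        for rec in records:
            if rec.smiles not in seen:
                seen.add(rec.smiles)
                unique.append(rec)
        parsed[name] = unique

    membership: dict[str, int] = {}
    for records in parsed.values():
        for rec in records:
            membership[rec.smiles] = membership.get(rec.smiles, 0) + 1
    promiscuous = {s for s, n in membership.items() if n > max_membership}

    families = []
    for name, records in parsed.items():
        fam = FragranceFamily(name, [], n_raw=len(records))
        for rec in records:
            if rec.smiles in promiscuous:
                fam.n_removed_promiscuous += 1
                continue
            if not _fl.is_fragrance_like(rec).passed:
                fam.n_removed_non_fl += 1
                continue
            if hac_cap is not None and rec.hac > hac_cap:
                fam.n_removed_hac_cap += 1
                continue
            fam.members.append(rec)
        if len(fam) >= min_size:
            families.append(fam)
    return families


def select_reference(
    family: FragranceFamily, space: str | DescriptorSpace
) -> str:
    """Per-space medoid: the member minimizing the summed distance to the rest.

    Ties break to the lowest id.
    """
    if isinstance(space, str):
        space = get_space(space)
    encoded = [space.encode(rec) for rec in family.members]
    n = len(encoded)
    if n == 1:
        return family.members[0].id
    totals = np.zeros(n)
    for i in range(n):
        for j in range(i + 1, n):
            d = space.distance(encoded[i], encoded[j])
            totals[i] += d
            totals[j] += d
    best = totals.min()
    # ties include float-noise ties from summation order (MW sums)
    tied = np.flatnonzero(np.isclose(totals, best, rtol=1e-12, atol=1e-7))
    return min(family.members[i].id for i in tied)


@dataclass
class EnrichmentResult:
    """Outcome of one family x space enrichment run."""

    family: str
    space: str
    reference_id: str
    ranking: list[tuple[str, float, bool]]  # (id, distance, is_active)
    roc: np.ndarray  # (m, 2) of (FPR, TPR) in [0, 1]
    auc: float  # percent
    recovery: dict[float, float]  # screened fraction -> recovered actives, percent
    n_actives: int = 0
    n_background: int = 0


def _roc_auc(distances: np.ndarray, is_active: np.ndarray) -> tuple[np.ndarray, float]:
    """ROC points and Mann-Whitney AUC (percent) for an ascending-distance
    ranking; tie groups step diagonally (ties counted half)."""
    n_a = int(is_active.sum())
    n_d = len(is_active) - n_a
    ranks = rankdata(distances)  # average ranks handle ties
    u_greater = ranks[is_active].sum() - n_a * (n_a + 1) / 2.0
    auc = 100.0 * (n_a * n_d - u_greater) / (n_a * n_d)

    order = np.argsort(distances, kind="stable")
    d_sorted = distances[order]
    a_sorted = is_active[order]
    points = [(0.0, 0.0)]
    tp = fp = 0
    i = 0
    n = len(d_sorted)
    while i < n:
        j = i
        while j < n and d_sorted[j] == d_sorted[i]:
            j += 1
        tp += int(a_sorted[i:j].sum())
        fp += int((~a_sorted[i:j]).sum())
        points.append((fp / n_d if n_d else 0.0, tp / n_a if n_a else 0.0))
        i = j
    return np.asarray(points), float(auc)


def run_enrichment(
    family: FragranceFamily,
    background: Sequence[MoleculeRecord],
    space: str | DescriptorSpace,
    fractions: Sequence[float] = DEFAULT_FRACTIONS,
    reference_id: str | None = None,
    include_reference: bool = False,
) -> EnrichmentResult:
    """Dilute a family's actives in a background database and score the
    distance ranking to the family reference.

    The reference is excluded from the actives and the ranked list unless
    ``include_reference`` is set.  Background entries whose canonical
    structure matches a family member are removed before dilution, so the
    two sets are disjoint.  Recovery at fraction ``f`` counts actives within
    the top ``max(1, floor(f * N))`` candidates of the ranking sorted by
    (distance, id) — the id order resolves ties at the cutoff.
    """
    if isinstance(space, str):
        space = get_space(space)
    if reference_id is None:
        reference_id = select_reference(family, space)
    reference = next(r for r in family.members if r.id == reference_id)

    actives = [r for r in family.members if r.id != reference_id]
    if include_reference:
        actives = list(family.members)
    if len(actives) < 2:
        raise ValueError("family has fewer than 2 actives after reference removal")

    family_smiles = {r.smiles for r in family.members}
    decoys = [r for r in background if r.smiles not in family_smiles]

    ref_vec = space.encode(reference)
    candidates = actives + decoys
    is_active = np.zeros(len(candidates), dtype=bool)
    is_active[: len(actives)] = True
    vectors = np.vstack([space.encode(r) for r in candidates])
    distances = space.distance_matrix(ref_vec, vectors).astype(float)

    roc, auc = _roc_auc(distances, is_active)

    ids = [r.id for r in candidates]
    order = sorted(range(len(candidates)), key=lambda i: (distances[i], ids[i]))
    ranking = [(ids[i], float(distances[i]), bool(is_active[i])) for i in order]

    n = len(candidates)
    n_act = len(actives)
    recovery = {}
    for f in fractions:
        cutoff = max(1, int(np.floor(f * n)))
        found = sum(1 for _, _, act in ranking[:cutoff] if act)
        recovery[f] = 100.0 * found / n_act
    recovery[1.0] = 100.0

    return EnrichmentResult(
        family=family.name,
        space=space.name,
        reference_id=reference_id,
        ranking=ranking,
        roc=roc,
        auc=auc,
        recovery=recovery,
        n_actives=n_act,
        n_background=len(decoys),
    )


def enrichment_table(
    results: Sequence[EnrichmentResult],
    families: Sequence[FragranceFamily] | None = None,
    fraction: float = 0.01,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Summarize results: per-family recovery per space (with the best space
    flagged per row) plus an Average row, and mean AUC +/- SD per space.
    """
    if not results:
        return (
            pd.DataFrame(columns=["family", "n_cpds", "hac_av"]),
            pd.DataFrame(columns=["space", "auc_mean", "auc_sd"]),
        )
    spaces = sorted({r.space for r in results})
    fam_info = {f.name: f for f in families or []}
    by_family: dict[str, dict[str, EnrichmentResult]] = {}
    for r in results:
        by_family.setdefault(r.family, {})[r.space] = r

    rows = []
    for fam_name, per_space in by_family.items():
        row: dict = {"family": fam_name}
        any_res = next(iter(per_space.values()))
        row["n_cpds"] = any_res.n_actives + 1
        fam = fam_info.get(fam_name)
        row["hac_av"] = round(fam.mean_hac, 2) if fam else np.nan
        for sp in spaces:
            res = per_space.get(sp)
            row[f"recov_{sp}"] = (
                round(res.recovery.get(fraction, np.nan), 1) if res else np.nan
            )
        recs = {sp: row[f"recov_{sp}"] for sp in spaces}
        best_val = np.nanmax(list(recs.values()))
        row["best"] = ",".join(sp for sp, v in recs.items() if v == best_val)
        rows.append(row)
    table = pd.DataFrame(rows)
    avg = {"family": "Average", "n_cpds": round(table["n_cpds"].mean(), 1),
           "hac_av": round(table["hac_av"].mean(), 2)}
    for sp in spaces:
        avg[f"recov_{sp}"] = round(table[f"recov_{sp}"].mean(), 1)
    avg_rec = {sp: avg[f"recov_{sp}"] for sp in spaces}
    avg["best"] = ",".join(
        sp for sp, v in avg_rec.items() if v == np.nanmax(list(avg_rec.values()))
    )
    table = pd.concat([table, pd.DataFrame([avg])], ignore_index=True)

    auc_rows = []
    for sp in spaces:
        aucs = [r.auc for r in results if r.space == sp]
        auc_rows.append(
            {
                "space": sp,
                "auc_mean": round(float(np.mean(aucs)), 2),
                "auc_sd": round(float(np.std(aucs, ddof=0)), 2),
            }
        )
    return table, pd.DataFrame(auc_rows)
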