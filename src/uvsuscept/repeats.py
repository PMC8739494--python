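"""Repeat-family quantification and the family-level differential test.

Reads hitting several repeat families are divided equally amongst them
(a read mapping to k families adds 1/k to each), so total read mass is
conserved.  Family-level differences between paired replicate groups are
scored with the Wilcoxon signed-rank statistic, a sign-flip permutation
p (exhaustive for up to 10 pairs), and Benjamini-Hochberg correction
across families.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .stats import bh_adjust


@dataclass
class FamilyCountVector:
    counts: dict[str, float] = field(default_factory=dict)
    unassigned: float = 0.0
    total_reads: int = 0

    def cpm(self) -> dict[str, float]:
        if self.total_reads == 0:
            raise ValueError("empty count vector")
        f = self.total_reads / 1e6
        return {fam: c / f for fam, c in self.counts.items()}


def assign_fractional(
    read_family_map: dict[str, frozenset[str]] | list[frozenset[str]],
) -> FamilyCountVector:
    """Divide each read equally amongst its candidate families.

    A read with an empty candidate set counts as unassigned.  Mass is
    conserved: family counts plus unassigned equal the number of reads.
    """
    fams_iter = (
        read_family_map.values()
        if isinstance(read_family_map, dict)
        else read_family_map
    )
    vec = FamilyCountVector()
    for fams in fams_iter:
        vec.total_reads += 1
        if not fams:
            vec.unassigned += 1.0
            continue
        share = 1.0 / len(fams)
        for fam in fams:
            vec.counts[fam] = vec.counts.get(fam, 0.0) + share
    return vec


def family_log2fc(
    ip: FamilyCountVector,
    input_: FamilyCountVector,
    pseudocount: float = 0.5,
) -> pd.Series:
    """Per-family ``log2((ip_cpm + pc) / (input_cpm + pc))``.

    Families absent from one vector are treated as zero there; swapping
    the vectors negates every value.
    """
    ip_cpm, in_cpm = ip.cpm(), input_.cpm()
    fams = sorted(set(ip_cpm) | set(in_cpm))
    vals = {
        fam: float(
            np.log2((ip_cpm.get(fam, 0.0) + pseudocount) / (in_cpm.get(fam, 0.0) + pseudocount))
        )
        for fam in fams
    }
    return pd.Series(vals, name="log2fc")


def _signed_rank_stat(d: np.ndarray) -> float:
    """Sum of signed ranks of |d|, zeros dropped, average ranks on ties."""
    d = d[d != 0]
    if len(d) == 0:
        return 0.0
    ranks = stats.rankdata(np.abs(d))
    return float(np.sum(np.sign(d) * ranks))


def sign_flip_permutation_p(
    d: np.ndarray, n_perm: int = 10_000, rng: np.random.Generator | None = None,
    exhaustive_max_pairs: int = 10,
) -> float:
    """Two-sided sign-flip permutation p for paired differences.

    The statistic is the signed-rank sum.  For up to
    ``exhaustive_max_pairs`` nonzero pairs all 2^n flips are enumerated
    and the p-value is the exact fraction with |statistic| >= observed;
    otherwise ``n_perm`` random flips are drawn and the add-one estimate
    ``(1 + hits) / (n_perm + 1)`` is returned.
    """
    d = np.asarray(d, dtype=float)
    obs = abs(_signed_rank_stat(d))
    nz = d[d != 0]
    n = len(nz)
    if n == 0:
        return 1.0
    ranks = stats.rankdata(np.abs(nz))
    if n <= exhaustive_max_pairs:
        hits = total = 0
        for signs in itertools.product((-1.0, 1.0), repeat=n):
            total += 1
            if abs(float(np.sum(np.asarray(signs) * ranks))) >= obs:
                hits += 1
        return hits / total
    rng = rng or np.random.default_rng()
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
    perm = np.abs(signs @ ranks)
    return (1 + int(np.sum(perm >= obs))) / (n_perm + 1)


def family_differential(
    paired_values: pd.DataFrame,
    n_perm: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Family-level paired comparison across replicate groups.

    ``paired_values`` is indexed by family with matched column pairs
    ``("a", i)`` / ``("b", i)`` (e.g. knockout vs wild-type log2 fold
    changes per replicate).  Per family: mean paired difference, Wilcoxon
    signed-rank p, sign-flip permutation p, and BH q across families.
    All-zero differences give p = 1.
    """
    a = paired_values["a"].to_numpy(dtype=float)
    b = paired_values["b"].to_numpy(dtype=float)
    if a.shape[1] < 2:
        raise ValueError("need >= 2 paired observations per family")
    rng = np.random.default_rng(seed)
    rows = []
    for fam, da, db in zip(paired_values.index, a, b):
        d = da - db
        if np.all(d == 0):
            p_w = 1.0
        else:
            p_w = float(stats.wilcoxon(da, db, zero_method="wilcox").pvalue)
        p_perm = sign_flip_permutation_p(d, n_perm=n_perm, rng=rng)
        rows.append(dict(family=fam, mean_diff=float(np.mean(d)),
                         p_wilcoxon=p_w, p_perm=p_perm))
    df = pd.DataFrame(rows).set_index("family")
    df["q"] = bh_adjust(df["p_perm"].to_numpy())
    return df
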