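"""Variant-rate estimation from per-site, per-worm base counts.

A clonal cohort should carry essentially no segregating variation; this
module quantifies that from mRNA-seq pileups.  Sites are kept when a
worm has >= 20 reads; base calls are classified as unambiguous (one base
observed), ambiguous with two bases, or multi (>2 bases, tallied but
never a candidate).  Candidate homozygous variants are (site, worm)
observations whose unambiguous base differs from another worm's
unambiguous base at a site covered in >= 10 worms; candidate
heterozygous variants are two-base observations with both allele
fractions in [0.3, 0.7] while >= 10 other worms are unambiguous for one
shared base (rare sequencing errors produce skewed fractions and are
excluded by the window).  Rates are candidates per site x worm
observation passing the coverage filters.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

__all__ = ["SiteCalls", "VariantRateReport", "classify_site_calls",
           "classify_site_calls_arrays",
           "candidate_homozygous", "candidate_heterozygous", "variant_rates",
           "read_sitecalls", "write_sitecalls", "read_samtools_pileup",
           "run_isogenicity_check"]

BASES = ("A", "C", "G", "T")


@dataclass
class SiteCalls:
    """Depth-filtered calls in compact array form.

    ``worm``/``site`` are integer codes into ``worm_ids``/``site_keys``;
    ``n_bases`` counts distinct observed bases; for two-base calls
    ``freq1`` >= ``freq2`` are the allele fractions and ``base1``/
    ``base2`` the base indices.  For unambiguous calls ``base1`` is the
    single observed base.
    """

    worm: np.ndarray
    site: np.ndarray
    n_bases: np.ndarray
    base1: np.ndarray
    base2: np.ndarray
    freq1: np.ndarray
    freq2: np.ndarray
    worm_ids: list
    site_keys: list  # (chrom, pos)


@dataclass
class VariantRateReport:
    sites_considered: int
    total_observations: int
    homozygous_candidates: int
    heterozygous_candidates: int
    homozygous_rate: float
    heterozygous_rate: float
    het_singleton_fraction: float

    def to_dict(self) -> dict:
        return asdict(self)


def read_sitecalls(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    need = ["worm_id", "chrom", "pos", "depth", "A", "C", "G", "T"]
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise ValueError(f"site-call table missing columns {missing}")
    return df


def write_sitecalls(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_samtools_pileup(path, worm_id: str) -> pd.DataFrame:
    """Convert basic samtools-mpileup text for one sample to a site-call table.

    Expects the classic 6-column format (chrom, pos, ref, depth, read
    bases, quals).  Handles match marks (``.``/``,``), explicit base
    calls, read start (``^`` + mapq char) and end (``$``) marks, and
    skips indel runs (``+``/``-`` followed by a length) and deletion
    placeholders (``*``); base counts are re-tallied from the read-base
    string, so the reported depth is the number of counted bases.
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 5:
                continue
            chrom, pos, ref = parts[0], int(parts[1]), parts[2].upper()
            bases = parts[4]
            counts = {b: 0 for b in BASES}
            i = 0
            while i < len(bases):
                ch = bases[i]
                if ch == "^":
                    i += 2  # skip the mapping-quality character
                    continue
                if ch in "$*<>":
                    i += 1
                    continue
                if ch in "+-":
                    j = i + 1
                    while j < len(bases) and bases[j].isdigit():
                        j += 1
                    i = j + int(bases[i + 1:j])
                    continue
                if ch in ".,":
                    if ref in counts:
                        counts[ref] += 1
                elif ch.upper() in counts:
                    counts[ch.upper()] += 1
                i += 1
            depth = sum(counts.values())
            rows.append((worm_id, chrom, pos, depth,
                         counts["A"], counts["C"], counts["G"], counts["T"]))
    return pd.DataFrame(rows, columns=["worm_id", "chrom", "pos", "depth",
                                       "A", "C", "G", "T"])


def classify_site_calls(table: pd.DataFrame, min_depth: int = 20) -> SiteCalls:
    """Drop observations below ``min_depth`` and classify the rest by the
    number of distinct bases with nonzero count."""
    counts = table[list(BASES)].values
    if (counts < 0).any():
        raise ValueError("negative base counts")
    depth = counts.sum(axis=1)
    keep = depth >= min_depth
    counts = counts[keep]
    depth = depth[keep]
    sub = table.loc[keep]

    worm_ids, worm_codes = np.unique(sub["worm_id"].values, return_inverse=True)
    site_df = sub[["chrom", "pos"]]
    site_keys, site_codes = np.unique(
        site_df["chrom"].astype(str).values + ":" + site_df["pos"].astype(str).values,
        return_inverse=True)

    order = np.argsort(counts, axis=1)[:, ::-1]
    sorted_counts = np.take_along_axis(counts, order, axis=1)
    n_bases = (counts > 0).sum(axis=1)
    freq1 = sorted_counts[:, 0] / depth
    freq2 = sorted_counts[:, 1] / depth
    return SiteCalls(
        worm=worm_codes.astype(np.int32),
        site=site_codes.astype(np.int64),
        n_bases=n_bases.astype(np.int8),
        base1=order[:, 0].astype(np.int8),
        base2=order[:, 1].astype(np.int8),
        freq1=freq1, freq2=freq2,
        worm_ids=list(worm_ids), site_keys=list(site_keys),
    )


def classify_site_calls_arrays(counts: np.ndarray, positions: np.ndarray,
                               min_depth: int = 20, chrom: str = "I",
                               worm_ids=None) -> SiteCalls:
    """Classify a dense (worms, sites, 4) base-count array.

    Memory-lean path for genome-scale simulations (tens of millions of
    site x worm observations), equivalent to :func:`classify_site_calls`
    on the long-format table.
    """
    if counts.ndim != 3 or counts.shape[2] != 4:
        raise ValueError("counts must have shape (worms, sites, 4)")
    if (counts < 0).any():
        raise ValueError("negative base counts")
    n_worms, n_sites, _ = counts.shape
    depth = counts.sum(axis=2)
    worm_g, site_g = np.nonzero(depth >= min_depth)
    sub = counts[worm_g, site_g]  # (m, 4)
    d = depth[worm_g, site_g].astype(float)

    order = np.argsort(sub, axis=1)[:, ::-1]
    sorted_counts = np.take_along_axis(sub, order, axis=1)
    n_bases = (sub > 0).sum(axis=1)
    if worm_ids is None:
        worm_ids = [f"worm{w:04d}" for w in range(n_worms)]
    return SiteCalls(
        worm=worm_g.astype(np.int32),
        site=site_g.astype(np.int64),
        n_bases=n_bases.astype(np.int8),
        base1=order[:, 0].astype(np.int8),
        base2=order[:, 1].astype(np.int8),
        freq1=sorted_counts[:, 0] / d,
        freq2=sorted_counts[:, 1] / d,
        worm_ids=list(worm_ids),
        site_keys=[f"{chrom}:{p}" for p in positions],
    )


def _covered_sites(calls: SiteCalls, min_worms_covered: int) -> np.ndarray:
    n_sites = len(calls.site_keys)
    cov = np.bincount(calls.site, minlength=n_sites)
    return cov >= min_worms_covered


def candidate_homozygous(calls: SiteCalls, min_worms_covered: int = 10,
                         min_discordant_worms: int = 1) -> pd.DataFrame:
    """Minority unambiguous calls at sites where worms disagree.

    Sites covered in fewer than ``min_worms_covered`` worms are excluded.
    A worm's unambiguous call is a candidate when it differs from the
    site's majority unambiguous base and at least
    ``min_discordant_worms`` other worms are unambiguous for a different
    base (so 10 worms reading A plus one reading G yield one candidate).
    """
    ok_site = _covered_sites(calls, min_worms_covered)
    unamb = (calls.n_bases == 1) & ok_site[calls.site]
    sites = calls.site[unamb]
    bases = calls.base1[unamb]
    worms = calls.worm[unamb]

    n_sites = len(calls.site_keys)
    per_base = np.zeros((n_sites, 4), dtype=np.int64)
    np.add.at(per_base, (sites, bases), 1)
    total_unamb = per_base.sum(axis=1)
    majority = per_base.argmax(axis=1)
    # worms unambiguous for a different base than this observation's base
    discordant = total_unamb[sites] - per_base[sites, bases]
    is_cand = (discordant >= min_discordant_worms) & (bases != majority[sites])
    out = pd.DataFrame({
        "site": [calls.site_keys[s] for s in sites[is_cand]],
        "worm_id": [calls.worm_ids[w] for w in worms[is_cand]],
        "base": [BASES[b] for b in bases[is_cand]],
    })
    return out


def candidate_heterozygous(calls: SiteCalls, freq_lo: float = 0.3,
                           freq_hi: float = 0.7,
                           min_unambiguous_others: int = 10,
                           min_worms_covered: int = 10
                           ) -> tuple[pd.DataFrame, float]:
    """Two-base observations in the allele-fraction window with enough
    unambiguous, concordant other worms; plus the singleton fraction.

    Returns the candidate table and the fraction of candidate sites
    whose candidates occur in exactly one worm.
    """
    ok_site = _covered_sites(calls, min_worms_covered)
    n_sites = len(calls.site_keys)

    unamb = calls.n_bases == 1
    per_base = np.zeros((n_sites, 4), dtype=np.int64)
    np.add.at(per_base, (calls.site[unamb], calls.base1[unamb]), 1)
    shared_max = per_base.max(axis=1)  # largest unambiguous-consensus count

    amb2 = ((calls.n_bases == 2) & ok_site[calls.site]
            & (calls.freq1 >= freq_lo) & (calls.freq1 <= freq_hi)
            & (calls.freq2 >= freq_lo) & (calls.freq2 <= freq_hi))
    # the ambiguous worm itself is never unambiguous, so no self-exclusion needed
    enough_others = shared_max[calls.site] >= min_unambiguous_others
    is_cand = amb2 & enough_others

    sites = calls.site[is_cand]
    out = pd.DataFrame({
        "site": [calls.site_keys[s] for s in sites],
        "worm_id": [calls.worm_ids[w] for w in calls.worm[is_cand]],
        "base1": [BASES[b] for b in calls.base1[is_cand]],
        "base2": [BASES[b] for b in calls.base2[is_cand]],
        "freq1": calls.freq1[is_cand],
        "freq2": calls.freq2[is_cand],
    })
    if len(out):
        per_site = out.groupby("site")["worm_id"].nunique()
        singleton_fraction = float((per_site == 1).mean())
    else:
        singleton_fraction = 0.0
    return out, singleton_fraction


def variant_rates(n_hom: int, n_het: int, calls: SiteCalls,
                  min_worms_covered: int = 10,
                  het_singleton_fraction: float = 0.0) -> VariantRateReport:
    """Rates per site x worm observation at sites passing the coverage rule."""
    ok_site = _covered_sites(calls, min_worms_covered)
    total = int(np.sum(ok_site[calls.site]))
    if total <= 0:
        raise ValueError("no observations pass the coverage filters")
    return VariantRateReport(
        sites_considered=int(ok_site.sum()),
        total_observations=total,
        homozygous_candidates=int(n_hom),
        heterozygous_candidates=int(n_het),
        homozygous_rate=n_hom / total,
        heterozygous_rate=n_het / total,
        het_singleton_fraction=het_singleton_fraction,
    )


def run_isogenicity_check(table: pd.DataFrame, min_depth: int = 20,
                          min_worms_covered: int = 10,
                          freq_lo: float = 0.3, freq_hi: float = 0.7
                          ) -> tuple[VariantRateReport, pd.DataFrame, pd.DataFrame]:
    """End-to-end: classify, find candidates, compute rates."""
    calls = classify_site_calls(table, min_depth=min_depth)
    hom = candidate_homozygous(calls, min_worms_covered=min_worms_covered)
    het, singleton = candidate_heterozygous(
        calls, freq_lo=freq_lo, freq_hi=freq_hi,
        min_unambiguous_others=min_worms_covered,
        min_worms_covered=min_worms_covered)
    report = variant_rates(len(hom), len(het), calls,
                           min_worms_covered=min_worms_covered,
                           het_singleton_fraction=singleton)
    return report, hom, het
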