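"""Protein-complex analysis: overrepresentation and subunit stoichiometry.

Complex-level overrepresentation uses a one-sided Fisher's exact test
(hypergeometric upper tail) on the quantified background with
Benjamini-Hochberg correction; complexes missing at least half of their
members from the background are removed before testing (the coverage
filter is applied against detected proteins).

Inter-subunit stoichiometry scales each subunit's intensity by its
theoretical number of fully-tryptic peptides within a length window —
the iBAQ convention — so that abundances become comparable between
proteins of different size, and reports each subunit relative to the mean
over detected complex members.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from pyteomics import parser as pyt_parser
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "count_tryptic_peptides",
    "peptide_count_table",
    "subunit_relative_abundance",
    "fisher_greater_p",
    "gene_set_enrichment",
]

#: cleave C-terminal to K or R unless the next residue is proline
TRYPSIN_RULE = r"[KR](?!P)"


def count_tryptic_peptides(
    sequence: str, min_len: int = 7, max_len: int = 30
) -> int:
    """Number of fully-tryptic peptides with length in ``[min_len, max_len]``.

    Cleavage occurs after K or R except when followed by P, with zero
    missed cleavages.  Repeated identical peptides are each counted.  An
    empty sequence yields 0 with a warning.
    """
    sequence = sequence.strip().upper()
    if not sequence:
        warnings.warn("empty sequence: peptide count is 0", stacklevel=2)
        return 0
    peptides = [
        pep for _, pep in pyt_parser.icleave(
            sequence, TRYPSIN_RULE, missed_cleavages=0
        )
    ]
    return sum(min_len <= len(p) <= max_len for p in peptides)


def peptide_count_table(
    sequences: dict[str, str], min_len: int = 7, max_len: int = 30
) -> pd.Series:
    """Theoretical tryptic-peptide counts for a sequence set."""
    return pd.Series(
        {
            label: count_tryptic_peptides(seq, min_len=min_len, max_len=max_len)
            for label, seq in sequences.items()
        },
        name="n_tryptic_peptides",
    ).rename_axis("Protein")


def subunit_relative_abundance(
    intensities: pd.Series,
    peptide_counts: pd.Series,
    complex_members: list[str],
) -> pd.DataFrame:
    """Peptide-count-scaled subunit abundances relative to the complex mean.

    Each detected member's intensity is divided by its theoretical peptide
    count, then by the mean scaled value over detected members.  Members
    without a quantified intensity are reported absent (NaN); members with
    a zero peptide count are excluded with a warning.
    """
    rows = []
    for member in complex_members:
        intensity = intensities.get(member, np.nan)
        count = peptide_counts.get(member, np.nan)
        if pd.notna(intensity) and count == 0:
            warnings.warn(
                f"subunit {member!r} has zero theoretical peptides; excluded",
                stacklevel=2,
            )
            intensity = np.nan
        scaled = intensity / count if pd.notna(intensity) and count else np.nan
        rows.append({"subunit": member, "scaled": scaled})
    frame = pd.DataFrame(rows)
    detected = frame["scaled"].notna()
    if detected.sum() < 2:
        raise ValueError("at least 2 detected complex members are required")
    frame["relative"] = frame["scaled"] / frame.loc[detected, "scaled"].mean()
    frame["detected"] = detected
    return frame


def fisher_greater_p(k: int, set_size: int, query_size: int, background: int) -> float:
    """One-sided (greater) Fisher's exact p for a 2x2 overrepresentation table.

    Equals the hypergeometric upper tail P(X >= k) for drawing
    ``query_size`` proteins from ``background`` of which ``set_size`` are
    set members.
    """
    table = [
        [k, query_size - k],
        [set_size - k, background - set_size - query_size + k],
    ]
    return float(stats.fisher_exact(table, alternative="greater")[1])


def gene_set_enrichment(
    query: set,
    catalog: dict[str, dict],
    background: set,
    coverage_min: float = 0.5,
) -> pd.DataFrame:
    """Background-restricted overrepresentation of each gene set.

    Requires ``query`` to be a subset of ``background``.  Sets whose
    detected fraction of members in the background is below
    ``coverage_min`` are excluded before testing; Benjamini-Hochberg q
    values are computed across the tested sets.
    """
    query, background = set(query), set(background)
    if not query <= background:
        raise ValueError("query must be a subset of the background")
    if len(background) < len(query):
        raise ValueError("background smaller than query")
    rows = []
    for set_id in sorted(catalog):
        members = catalog[set_id]["members"]
        detected = set(members) & background
        detected_fraction = len(detected) / len(members)
        if detected_fraction < coverage_min:
            continue
        k = len(detected & query)
        set_size = len(detected)
        p = fisher_greater_p(k, set_size, len(query), len(background))
        a, b = k, len(query) - k
        c, d = set_size - k, len(background) - set_size - len(query) + k
        odds = np.inf if (b == 0 or c == 0) and a * d > 0 else (
            (a * d) / (b * c) if b * c else np.nan
        )
        rows.append(
            {
                "set_id": set_id,
                "name": catalog[set_id]["name"],
                "overlap": k,
                "query_size": len(query),
                "set_size": set_size,
                "background_size": len(background),
                "odds_ratio": odds,
                "p_value": p,
                "detected_fraction": detected_fraction,
            }
        )
    result = pd.DataFrame(
        rows,
        columns=[
            "set_id", "name", "overlap", "query_size", "set_size",
            "background_size", "odds_ratio", "p_value", "detected_fraction",
        ],
    )
    if len(result):
        result["q_value"] = multipletests(
            result["p_value"].to_numpy(), method="fdr_bh"
        )[1]
        result["q_value"] = np.maximum(result["q_value"], result["p_value"])
        result = result.sort_values(
            ["p_value", "set_id"], kind="mergesort"
        ).reset_index(drop=True)
    else:
        result["q_value"] = pd.Series(dtype=float)
    return result
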