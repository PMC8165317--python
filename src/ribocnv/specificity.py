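"""In-silico screening of ribotype-specific qPCR primer pairs.

Assay specificity is emulated by mismatch counting: a primer anneals at a
site when it has at most ``max_mismatch`` mismatches and a perfect match
in its 3'-terminal window; a pair amplifies a template when a forward site
and a downstream reverse site give a product within ``product_range``.
No thermodynamic modelling is attempted — empirical cross-amplification
screening is what mismatch counting stands in for.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._seq import encode, revcomp, validate_dna

MIN_PRIMER_LENGTH = 15


@dataclasses.dataclass(frozen=True)
class PrimerPair:
    """A qPCR primer pair plus its in-silico annealing rule.

    ``forward`` and ``reverse`` are both written 5'->3'; the reverse primer
    binds the template in reverse-complement orientation.  ``three_prime_window``
    bases at each primer's 3' end must match perfectly.
    """

    assay: str
    forward: str
    reverse: str
    max_mismatch: int = 2
    three_prime_window: int = 3
    product_range: tuple[int, int] = (50, 1500)

    def __post_init__(self) -> None:
        validate_dna(self.forward, name="forward primer")
        validate_dna(self.reverse, name="reverse primer")
        if min(len(self.forward), len(self.reverse)) < MIN_PRIMER_LENGTH:
            raise ValueError(f"primer lengths must be >= {MIN_PRIMER_LENGTH}")
        if self.three_prime_window > min(len(self.forward), len(self.reverse)):
            raise ValueError("three_prime_window exceeds primer length")


def _annealing_sites(
    primer: str, template_codes: np.ndarray, max_mismatch: int, window: int, *, window_at_end: bool
) -> np.ndarray:
    """Start positions where the primer (plus strand sequence) anneals.

    ``window_at_end`` selects which side of the site must be perfect: the
    3' end of a forward primer is its last bases; a reverse primer mapped
    to the plus strand has its 3' end at the start of the site.
    """
    p = encode(primer)
    lp = p.size
    n_sites = template_codes.size - lp + 1
    if n_sites <= 0:
        return np.empty(0, dtype=int)
    windows = np.lib.stride_tricks.sliding_window_view(template_codes, lp)
    mismatch = (windows != p).sum(axis=1)
    ok = mismatch <= max_mismatch
    if window > 0:
        region = slice(lp - window, lp) if window_at_end else slice(0, window)
        ok &= (windows[:, region] == p[region]).all(axis=1)
    return np.flatnonzero(ok)


def predict_amplification(pair: PrimerPair, template: str) -> tuple[bool, int | None]:
    """Does the pair amplify the template, and with what product length?

    Amplification requires a forward site and a downstream reverse site,
    each within the pair's mismatch/3'-window rule, with product length in
    ``product_range``.  The shortest qualifying product is reported.  The
    check is strand-symmetric: a template and its reverse complement give
    identical results (the primer roles swap).
    """
    validate_dna(template, name="template")
    products = [
        p
        for p in (
            _predict_plus_strand(pair, template),
            _predict_plus_strand(pair, revcomp(template)),
        )
        if p is not None
    ]
    if not products:
        return False, None
    return True, min(products)


def _predict_plus_strand(pair: PrimerPair, template: str) -> int | None:
    codes = encode(template)
    fwd_sites = _annealing_sites(
        pair.forward, codes, pair.max_mismatch, pair.three_prime_window, window_at_end=True
    )
    rev_site_seq = revcomp(pair.reverse)
    rev_sites = _annealing_sites(
        rev_site_seq, codes, pair.max_mismatch, pair.three_prime_window, window_at_end=False
    )
    if fwd_sites.size == 0 or rev_sites.size == 0:
        return None
    lo, hi = pair.product_range
    lr = len(pair.reverse)
    best: int | None = None
    for pf in fwd_sites:
        for qr in rev_sites[rev_sites >= pf]:
            product = int(qr + lr - pf)
            if lo <= product <= hi and (best is None or product < best):
                best = product
    return best


def cross_amplification_matrix(
    assays: Sequence[PrimerPair],
    templates: Mapping[str, str] | Iterable,
) -> pd.DataFrame:
    """Assay x template amplification flags.

    A fully specific assay set yields a diagonal-only matrix; a universal
    assay (targeting the conserved 5.8S) yields an all-true row.
    """
    if hasattr(templates, "items"):
        tmap = {k: getattr(v, "its_sequence", v) for k, v in templates.items()}
    else:
        tmap = {t.label: t.its_sequence for t in templates}
    if not assays or not tmap:
        raise ValueError("assays and templates must be non-empty")
    data = {
        pair.assay: {
            label: predict_amplification(pair, seq)[0] for label, seq in tmap.items()
        }
        for pair in assays
    }
    return pd.DataFrame(data).T.loc[[p.assay for p in assays], list(tmap)]


def select_discriminative_windows(
    alignment: Mapping[str, str], window_length: int = 20
) -> pd.DataFrame:
    """Rank candidate primer windows by cross-ribotype discrimination.

    For every target sequence and window start, the score is the minimum
    mismatch count between the target window and the homologous window of
    every non-target.  Rows are sorted per target by score (descending)
    then start (ascending).  All-zero scores mean no specific assay exists.
    """
    labels = list(alignment)
    if len(labels) < 2:
        raise ValueError("need at least two aligned sequences")
    lengths = {len(s) for s in alignment.values()}
    if len(lengths) != 1:
        raise ValueError("aligned sequences must have equal length")
    (aln_len,) = lengths
    if window_length > aln_len:
        raise ValueError("window_length exceeds alignment length")
    codes = {k: encode(v) for k, v in alignment.items()}
    n_win = aln_len - window_length + 1
    kernel = np.ones(window_length, dtype=int)
    rows = []
    for target in labels:
        per_site = [
            (codes[target] != codes[other]).astype(int)
            for other in labels
            if other != target
        ]
        window_mm = np.vstack([np.convolve(d, kernel, mode="valid") for d in per_site])
        score = window_mm.min(axis=0)
        for start in range(n_win):
            rows.append({"target": target, "start": start, "min_mismatches": int(score[start])})
    out = pd.DataFrame(rows)
    out = out.sort_values(
        ["target", "min_mismatches", "start"], ascending=[True, False, True], ignore_index=True
    )
    if (out.groupby("target")["min_mismatches"].max() == 0).any():
        warnings.warn("some target has no discriminative window; no specific assay exists", stacklevel=2)
    return out


def design_assay(
    target: str,
    alignment: Mapping[str, str],
    *,
    primer_length: int = 20,
    max_mismatch: int = 2,
    three_prime_window: int = 3,
    product_range: tuple[int, int] = (50, 1500),
) -> PrimerPair:
    """Design a target-specific pair on the most discriminative windows.

    Both primers are placed on windows whose minimum mismatch count to every
    non-target exceeds ``max_mismatch``, guaranteeing in-silico specificity
    under the screening rule; raises if no such window pair exists.
    """
    ranked = select_discriminative_windows(alignment, primer_length)
    mine = ranked[ranked["target"] == target]
    good = mine[mine["min_mismatches"] > max_mismatch].sort_values("start")
    starts = good["start"].to_numpy()
    seq = alignment[target]
    for w1 in starts:
        for w2 in starts[starts >= w1 + primer_length]:
            product = int(w2 + primer_length - w1)
            if product_range[0] <= product <= product_range[1]:
                return PrimerPair(
                    assay=target,
                    forward=seq[w1 : w1 + primer_length],
                    reverse=revcomp(seq[w2 : w2 + primer_length]),
                    max_mismatch=max_mismatch,
                    three_prime_window=three_prime_window,
                    product_range=product_range,
                )
    raise ValueError(f"no specific primer-pair placement exists for target {target!r}")


def design_universal_assay(
    template: str,
    conserved_interval: tuple[int, int],
    *,
    primer_length: int = 20,
    assay: str = "universal",
    product_range: tuple[int, int] = (50, 1500),
) -> PrimerPair:
    """Place both primers inside a conserved interval (e.g. the 5.8S gene).

    Such a pair amplifies every ribotype sharing that conserved region —
    the universal total-nrDNA assay.
    """
    start, end = conserved_interval
    if end - start < 2 * primer_length + 10:
        raise ValueError("conserved interval too short for a primer pair")
    forward = template[start : start + primer_length]
    reverse = revcomp(template[end - primer_length : end])
    return PrimerPair(assay=assay, forward=forward, reverse=reverse, product_range=product_range)
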