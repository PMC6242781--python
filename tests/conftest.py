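"""Shared fixtures and independent oracles used across the test suite."""

from __future__ import annotations

import math

import pytest

from signet.align import Alignment
from signet.synthetic import PanelSpec, simulate_panel

NEG_INF = float("-inf")


# --- independent oracles ----------------------------------------------------


def brute_force_global_score(x: str, y: str, match, mismatch, gap_open, gap_extend):
    """Optimal affine-gap global alignment score by exhaustive path search.

    Enumerates every monotone alignment path (feasible for len <= ~7),
    charging gap_open + k*gap_extend for each maximal gap of length k.
    Written independently of the production aligner.
    """
    best = [NEG_INF]

    def step(i: int, j: int, last: str, score: float) -> None:
        if i == len(x) and j == len(y):
            best[0] = max(best[0], score)
            return
        if i < len(x) and j < len(y):
            s = match if x[i] == y[j] else mismatch
            step(i + 1, j + 1, "M", score + s)
        if i < len(x):
            cost = gap_extend + (gap_open if last != "X" else 0)
            step(i + 1, j, "X", score + cost)
        if j < len(y):
            cost = gap_extend + (gap_open if last != "Y" else 0)
            step(i, j + 1, "Y", score + cost)

    step(0, 0, "M", 0.0)
    return best[0]


def naive_diagnostic_columns(rows, target, fixedness=1.0):
    """Column-by-column diagnostic scan on equal-length ungapped rows.

    ``rows`` is [(species, seq), ...]. Returns sorted column indices where
    >= fixedness of target rows share a concrete base absent from every
    non-target row. Independent reimplementation used as the oracle.
    """
    length = len(rows[0][1])
    out = []
    for col in range(length):
        tchars = [seq[col] for sp, seq in rows if sp == target]
        informative = [c for c in tchars if c not in "-N"]
        if not informative:
            continue
        # majority allele
        alleles = sorted(set(informative))
        allele = max(alleles, key=lambda a: (informative.count(a), a))
        if allele not in "ACGT":
            continue
        if informative.count(allele) / len(informative) < fixedness:
            continue
        ambig = {
            "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
            "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
        }
        bad = False
        for sp, seq in rows:
            if sp == target:
                continue
            c = seq[col]
            if c == allele or allele in ambig.get(c, ""):
                bad = True
                break
        if not bad:
            out.append(col)
    return out


def best_local_ungapped(query: str, subject: str, match=1, mismatch=-2) -> int:
    """Exhaustive ungapped local alignment score: per-diagonal Kadane scan."""
    best = 0
    for offset in range(-len(query) + 1, len(subject)):
        cur = 0
        for qi in range(len(query)):
            si = qi + offset
            if not (0 <= si < len(subject)):
                continue
            cur += match if query[qi] == subject[si] else mismatch
            if cur < 0:
                cur = 0
            best = max(best, cur)
    return best


def ols_slope_intercept(xs, ys):
    """Closed-form simple least squares from explicit sums."""
    n = len(xs)
    sx = sum(xs)
    sy = sum(ys)
    sxx = sum(x * x for x in xs)
    sxy = sum(x * y for x, y in zip(xs, ys))
    b = (n * sxy - sx * sy) / (n * sxx - sx * sx)
    a = (sy - b * sx) / n
    return a, b


# SantaLucia & Hicks (2004) unified nearest-neighbor parameters
_NN_DH = {
    "AA": -7.6, "AT": -7.2, "TA": -7.2, "CA": -8.5, "GT": -8.4,
    "CT": -7.8, "GA": -8.2, "CG": -10.6, "GC": -9.8, "GG": -8.0,
}
_NN_DS = {
    "AA": -21.3, "AT": -20.4, "TA": -21.3, "CA": -22.7, "GT": -22.4,
    "CT": -21.0, "GA": -22.2, "CG": -27.2, "GC": -24.4, "GG": -19.9,
}


def santalucia_tm(seq: str, na_mM=50.0, oligo_nM=250.0) -> float:
    """Independent nearest-neighbor Tm (deg C), SantaLucia unified set.

    Duplex initiation dH 0.2 / dS -5.7 plus a 2.2/6.9 penalty per terminal
    A-T pair; salt correction dS += 0.368*(N-1)*ln[Na+]; CT/4 concentration
    term for non-self-complementary duplexes.
    """
    comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
    dh, ds = 0.2, -5.7  # duplex initiation (dH kcal/mol, dS cal/mol/K)
    for terminal in (seq[0], seq[-1]):
        if terminal in "AT":
            dh += 2.2
            ds += 6.9
    for i in range(len(seq) - 1):
        pair = seq[i : i + 2]
        if pair not in _NN_DH:
            pair = comp[seq[i + 1]] + comp[seq[i]]  # reverse complement NN
        dh += _NN_DH[pair]
        ds += _NN_DS[pair]
    ds += 0.368 * (len(seq) - 1) * math.log(na_mM / 1000.0)
    ct = oligo_nM * 1e-9
    return dh * 1000.0 / (ds + 1.987 * math.log(ct / 4.0)) - 273.15


# --- fixtures ---------------------------------------------------------------


@pytest.fixture
def planted_panel():
    """4-species panel, 3 seqs each, two diagnostic sites planted in S2."""
    spec = PanelSpec(
        seed=42,
        n_species=4,
        n_seq_per_species=3,
        seq_length=200,
        interspecies_divergence=0.04,
        intraspecies_divergence=0.0,
        planted_sites={"S2": [(90, "A"), (110, "G")]},
    )
    return simulate_panel(spec)


@pytest.fixture
def planted_alignment(planted_panel):
    return Alignment.from_equal_length(planted_panel.records)
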