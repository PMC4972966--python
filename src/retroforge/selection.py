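"""Pairwise dN/dS estimation and the fixed-omega likelihood-ratio test.

The aligned region of each retrogene/parent protein alignment is
back-translated to a codon alignment, then the dN/dS ratio (omega) is
estimated twice by maximum likelihood under a single-omega codon model
(equal codon frequencies by default, transition/transversion ratio kappa
and branch length t estimated): once with omega free and once with omega
fixed at 0.5 -- the null of a neutrally decaying retrocopy.  Twice the
log-likelihood difference is referred to a chi-square with one degree of
freedom; a retrogene is called functionally constrained when omega < 0.5
and the test rejects.  Nei-Gojobori (1986) pathway counting with
Jukes-Cantor correction is provided as an independent, closed-form
cross-check of the ML estimates.  Very large dS (> 3 by default) flags
likely saturation of synonymous sites; such pairs are reported but not
called functional.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy.linalg import eigh
from scipy.optimize import minimize
from scipy.stats import chi2

from .homology import AlignmentHit

__all__ = [
    "CodonAlignment",
    "DnDsResult",
    "backtranslate",
    "ng86_counts",
    "estimate_dnds",
    "simulate_codon_pair",
    "choose_representative_parent",
    "functionality_screen",
]

NT = "ACGT"
_CODON_TABLE = {}
for _c in itertools.product(NT, repeat=3):
    _codon = "".join(_c)
    _CODON_TABLE[_codon] = None
_AA = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L", "CTT": "L", "CTC": "L", "CTA": "L",
    "CTG": "L", "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M", "GTT": "V", "GTC": "V",
    "GTA": "V", "GTG": "V", "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S", "CCT": "P",
    "CCC": "P", "CCA": "P", "CCG": "P", "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A", "TAT": "Y", "TAC": "Y", "TAA": "*",
    "TAG": "*", "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q", "AAT": "N", "AAC": "N",
    "AAA": "K", "AAG": "K", "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E", "TGT": "C",
    "TGC": "C", "TGA": "*", "TGG": "W", "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R", "GGT": "G", "GGC": "G", "GGA": "G",
    "GGG": "G",
}
SENSE_CODONS = tuple(c for c in sorted(_AA) if _AA[c] != "*")
_IDX = {c: i for i, c in enumerate(SENSE_CODONS)}
N_CODONS = len(SENSE_CODONS)  # 61

_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


def _model_structure():
    """Static (i, j) structure of single-nucleotide codon exchanges."""
    ii, jj, is_ts, is_syn = [], [], [], []
    for i, ci in enumerate(SENSE_CODONS):
        for j, cj in enumerate(SENSE_CODONS):
            if i == j:
                continue
            diffs = [(a, b) for a, b in zip(ci, cj) if a != b]
            if len(diffs) != 1:
                continue
            ii.append(i)
            jj.append(j)
            is_ts.append(diffs[0] in _TRANSITIONS)
            is_syn.append(_AA[ci] == _AA[cj])
    return (
        np.array(ii),
        np.array(jj),
        np.array(is_ts, dtype=bool),
        np.array(is_syn, dtype=bool),
    )


_II, _JJ, _IS_TS, _IS_SYN = _model_structure()


@dataclass
class CodonAlignment:
    """A pair of gap-aligned, in-frame coding sequences."""

    seq_a: str  # gapped, length divisible by 3
    seq_b: str
    id_a: str = "a"
    id_b: str = "b"

    def __post_init__(self) -> None:
        if len(self.seq_a) != len(self.seq_b) or len(self.seq_a) % 3 != 0:
            raise ValueError("codon alignment must be two equal-length in-frame sequences")

    def codon_pairs(self) -> list[tuple[str, str]]:
        """Ungapped aligned codon columns (both codons sense, no gaps)."""
        out = []
        for k in range(0, len(self.seq_a), 3):
            ca, cb = self.seq_a[k : k + 3], self.seq_b[k : k + 3]
            if "-" in ca or "-" in cb:
                continue
            if _AA.get(ca, "*") == "*" or _AA.get(cb, "*") == "*":
                continue
            out.append((ca, cb))
        return out

    @property
    def n_codons(self) -> int:
        return len(self.codon_pairs())


@dataclass
class DnDsResult:
    dn: float
    ds: float
    omega: float
    lnl_free: float
    lnl_fixed: float
    lrt_statistic: float
    p_value: float
    kappa: float = float("nan")
    t: float = float("nan")
    saturated: bool = False
    ds_defined: bool = True
    functional_call: bool = False


def backtranslate(hit: AlignmentHit, cds_a: str, cds_b: str) -> CodonAlignment:
    """Turn a protein alignment into the corresponding codon alignment.

    Only the aligned region is used; amino-acid gaps become whole-codon
    gaps.  Each aligned residue must match the translation of its codon,
    otherwise the offending column is reported.
    """
    cols_a, cols_b = [], []
    prev_q = prev_s = None
    for col, (q, s) in enumerate(hit.residue_map):
        if prev_q is not None and (q - prev_q > 1 or s - prev_s > 1):
            # unaligned stretch between blocks: emit codon gaps on the
            # shorter side so both sequences stay in frame
            for qq in range(prev_q + 1, q):
                cols_a.append(cds_a[3 * (qq - 1) : 3 * qq])
                cols_b.append("---")
            for ss in range(prev_s + 1, s):
                cols_a.append("---")
                cols_b.append(cds_b[3 * (ss - 1) : 3 * ss])
        ca = cds_a[3 * (q - 1) : 3 * q]
        cb = cds_b[3 * (s - 1) : 3 * s]
        if len(ca) < 3 or len(cb) < 3:
            raise ValueError(f"alignment column {col + 1}: residue beyond CDS end")
        cols_a.append(ca)
        cols_b.append(cb)
        prev_q, prev_s = q, s
    return CodonAlignment("".join(cols_a), "".join(cols_b), hit.query_id, hit.subject_id)


def check_backtranslation(hit: AlignmentHit, cds: str, protein: str, which: str = "query") -> None:
    """Raise when an aligned residue disagrees with its codon's translation."""
    for col, (q, s) in enumerate(hit.residue_map):
        r = q if which == "query" else s
        codon = cds[3 * (r - 1) : 3 * r]
        if _AA.get(codon, "X") != protein[r - 1]:
            raise ValueError(
                f"{which} column {col + 1}: codon {codon} translates to "
                f"{_AA.get(codon, 'X')} but aligned residue is {protein[r - 1]}"
            )


# ---------------------------------------------------------------------------
# Nei-Gojobori 1986 counting
# ---------------------------------------------------------------------------

def _codon_sites(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site fractions of one codon.

    Mutations to stop codons are excluded from the denominator, the
    standard convention.
    """
    syn = 0.0
    n_valid = 0
    for pos in range(3):
        s_pos = 0.0
        valid = 0
        for nt in NT:
            if nt == codon[pos]:
                continue
            alt = codon[:pos] + nt + codon[pos + 1 :]
            if _AA[alt] == "*":
                continue
            valid += 1
            if _AA[alt] == _AA[codon]:
                s_pos += 1
        if valid:
            syn += s_pos / valid
        n_valid += 1
    return syn, 3.0 - syn


def _pathway_counts(ca: str, cb: str) -> tuple[float, float]:
    """(syn, nonsyn) differences averaged over minimal mutational pathways;
    pathways passing through a stop codon are discarded."""
    diffs = [p for p in range(3) if ca[p] != cb[p]]
    if not diffs:
        return 0.0, 0.0
    results = []
    for order in itertools.permutations(diffs):
        cur = ca
        syn = nonsyn = 0
        ok = True
        for pos in order:
            nxt = cur[:pos] + cb[pos] + cur[pos + 1 :]
            if _AA[nxt] == "*":
                ok = False
                break
            if _AA[nxt] == _AA[cur]:
                syn += 1
            else:
                nonsyn += 1
            cur = nxt
        if ok:
            results.append((syn, nonsyn))
    if not results:  # all pathways hit a stop: count them anyway
        for order in itertools.permutations(diffs):
            cur = ca
            syn = nonsyn = 0
            for pos in order:
                nxt = cur[:pos] + cb[pos] + cur[pos + 1 :]
                if _AA[nxt] == _AA[cur]:
                    syn += 1
                else:
                    nonsyn += 1
                cur = nxt
            results.append((syn, nonsyn))
    s = sum(r[0] for r in results) / len(results)
    n = sum(r[1] for r in results) / len(results)
    return s, n


def _jc_correct(p: float) -> float:
    if p >= 0.75:
        return float("inf")
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def ng86_counts(ca: CodonAlignment) -> dict[str, float]:
    """Nei-Gojobori site and difference counts plus corrected pN/pS.

    Returns N_sites, S_sites, Nd, Sd, pN, pS, dN, dS and omega (dN/dS).
    """
    pairs = ca.codon_pairs()
    if not pairs:
        raise ValueError("no ungapped codon columns")
    S_sites = N_sites = Sd = Nd = 0.0
    for a, b in pairs:
        sa, na = _codon_sites(a)
        sb, nb = _codon_sites(b)
        S_sites += (sa + sb) / 2.0
        N_sites += (na + nb) / 2.0
        s, n = _pathway_counts(a, b)
        Sd += s
        Nd += n
    pS = Sd / S_sites if S_sites > 0 else float("nan")
    pN = Nd / N_sites if N_sites > 0 else float("nan")
    dS = _jc_correct(pS) if S_sites > 0 else float("nan")
    dN = _jc_correct(pN) if N_sites > 0 else float("nan")
    omega = dN / dS if dS and dS > 0 and not math.isinf(dS) else float("nan")
    return {
        "N_sites": N_sites, "S_sites": S_sites, "Nd": Nd, "Sd": Sd,
        "pN": pN, "pS": pS, "dN": dN, "dS": dS, "omega": omega,
    }


# ---------------------------------------------------------------------------
# ML codon model (single omega, equal codon frequencies)
# ---------------------------------------------------------------------------

def _rate_matrix(kappa: float, omega: float) -> tuple[np.ndarray, float, float]:
    """Normalized symmetric rate matrix plus the proportions of synonymous
    and nonsynonymous flux (rho_S, rho_N) under the given parameters."""
    rates = np.where(_IS_TS, kappa, 1.0) * np.where(_IS_SYN, 1.0, omega)
    Q = np.zeros((N_CODONS, N_CODONS))
    Q[_II, _JJ] = rates
    pi = 1.0 / N_CODONS
    flux = pi * rates
    total = flux.sum()
    rho_s = flux[_IS_SYN].sum() / total
    Q /= total  # one expected substitution per codon per unit time
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q, rho_s, 1.0 - rho_s


def _pair_counts(ca: CodonAlignment) -> np.ndarray:
    counts = np.zeros((N_CODONS, N_CODONS))
    for a, b in ca.codon_pairs():
        counts[_IDX[a], _IDX[b]] += 1.0
    return counts


def _log_likelihood(counts: np.ndarray, t: float, kappa: float, omega: float) -> float:
    Q, _, _ = _rate_matrix(kappa, omega)
    # Q is symmetric under equal frequencies: use the spectral decomposition
    w, V = eigh(Q)
    P = (V * np.exp(w * t)) @ V.T
    P = np.clip(P, 1e-300, None)
    pi = 1.0 / N_CODONS
    return float((counts * (math.log(pi) + np.log(P))).sum())


def estimate_dnds(
    ca: CodonAlignment,
    fix_omega: float | None = None,
    alpha: float = 0.05,
    saturation_ds: float = 3.0,
    min_codons: int = 10,
) -> DnDsResult:
    """ML dN/dS with a likelihood-ratio test against omega fixed at 0.5.

    Both fits share kappa and t as free parameters; the free fit adds
    omega.  dN and dS are derived from the fitted branch length and the
    model's synonymous/nonsynonymous flux proportions, per-site
    denominators taken at omega = 1.
    """
    counts = _pair_counts(ca)
    n = counts.sum()
    if n < min_codons:
        raise ValueError(f"need >= {min_codons} aligned codons, got {int(n)}")
    fix = 0.5 if fix_omega is None else fix_omega

    def neg_free(x):
        t, k, w = np.exp(x)
        return -_log_likelihood(counts, t, k, w)

    def neg_fixed(x):
        t, k = np.exp(x)
        return -_log_likelihood(counts, t, k, fix)

    ng = ng86_counts(ca)
    t0 = max(1e-3, (ng["dN"] if math.isfinite(ng["dN"]) else 0.1) * 3 + (ng["dS"] if math.isfinite(ng["dS"]) else 0.1))
    w0 = ng["omega"] if math.isfinite(ng["omega"]) and ng["omega"] > 0 else 0.5
    res_fixed = minimize(neg_fixed, np.log([t0, 2.0]), method="Nelder-Mead",
                         options={"xatol": 1e-5, "fatol": 1e-8, "maxiter": 400})
    # start the free fit from the fixed optimum so the free lnL can never be lower
    starts = [
        np.array([res_fixed.x[0], res_fixed.x[1], math.log(fix)]),
        np.log([t0, 2.0, max(w0, 1e-3)]),
    ]
    res_free = None
    for x0 in starts:
        r = minimize(neg_free, x0, method="Nelder-Mead",
                     options={"xatol": 1e-5, "fatol": 1e-8, "maxiter": 600})
        if res_free is None or r.fun < res_free.fun:
            res_free = r
    lnl_free = -res_free.fun
    lnl_fixed = -res_fixed.fun
    t, kappa, omega = np.exp(res_free.x)
    lrt = max(0.0, 2.0 * (lnl_free - lnl_fixed))
    p = float(chi2.sf(lrt, df=1))

    # convert (t, kappa, omega) to dN and dS
    _, rho_s, rho_n = _rate_matrix(kappa, omega)
    _, rho_s1, rho_n1 = _rate_matrix(kappa, 1.0)
    S_per_codon = 3.0 * rho_s1
    N_per_codon = 3.0 * rho_n1
    ds = t * rho_s / S_per_codon if S_per_codon > 0 else float("nan")
    dn = t * rho_n / N_per_codon if N_per_codon > 0 else float("nan")
    ds_defined = math.isfinite(ds) and S_per_codon > 0
    saturated = ds_defined and ds > saturation_ds
    return DnDsResult(
        dn=float(dn), ds=float(ds), omega=float(omega),
        lnl_free=lnl_free, lnl_fixed=lnl_fixed,
        lrt_statistic=lrt, p_value=p, kappa=float(kappa), t=float(t),
        saturated=saturated, ds_defined=ds_defined,
        functional_call=bool(omega < fix and p < alpha and not saturated and ds_defined),
    )


def simulate_codon_pair(t: float, kappa: float, omega: float, n_codons: int, rng) -> CodonAlignment:
    """Draw an aligned codon pair under the model (for calibration tests)."""
    Q, _, _ = _rate_matrix(kappa, omega)
    w, V = eigh(Q)
    P = (V * np.exp(w * t)) @ V.T
    P = np.clip(P, 0.0, None)
    P /= P.sum(axis=1, keepdims=True)
    anc = rng.integers(0, N_CODONS, size=n_codons)
    seq_a, seq_b = [], []
    for i in anc:
        seq_a.append(SENSE_CODONS[i])
        j = rng.choice(N_CODONS, p=P[i])
        seq_b.append(SENSE_CODONS[j])
    return CodonAlignment("".join(seq_a), "".join(seq_b))


def choose_representative_parent(ds_by_parent: dict[str, float]) -> str:
    """Parent with the smallest dS; ties break to the smaller gene id.

    Non-finite dS values sort last but a candidate with only saturated or
    undefined dS still gets its minimum chosen (flagged upstream).
    """
    if not ds_by_parent:
        raise ValueError("no parents supplied")
    return min(
        ds_by_parent,
        key=lambda p: (not math.isfinite(ds_by_parent[p]), ds_by_parent[p], p),
    )


def functionality_screen(
    results: dict[str, DnDsResult], alpha: float = 0.05, ignore_saturation: bool = False
) -> dict[str, bool]:
    """Functional-constraint call per candidate: omega < 0.5, LRT p < alpha,
    and (unless overridden) dS below the saturation threshold."""
    out = {}
    for cid, r in results.items():
        ok = r.omega < 0.5 and r.p_value < alpha and r.ds_defined
        if not ignore_saturation:
            ok = ok and not r.saturated
        out[cid] = bool(ok)
    return out
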