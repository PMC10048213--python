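"""Independent brute-force oracles used only by tests.

Deliberately written in plain scalar Python (loops, Fractions) with no code
shared with the package, so that agreement with the vectorized
implementations is evidence, not tautology.
"""

from __future__ import annotations

import math
from fractions import Fraction
from typing import Dict, List, Sequence, Set, Tuple


def dl_reference(betas: Sequence[float], ses: Sequence[float]) -> Dict[str, float]:
    """Loop-based DerSimonian-Laird pool of log odds ratios."""
    k = len(betas)
    weights = [1.0 / (s * s) for s in ses]
    sw = sum(weights)
    beta_fixed = sum(w * b for w, b in zip(weights, betas)) / sw
    q = sum(w * (b - beta_fixed) ** 2 for w, b in zip(weights, betas))
    sw2 = sum(w * w for w in weights)
    denom = sw - sw2 / sw
    tau2 = (q - (k - 1)) / denom if denom > 0 else 0.0
    if tau2 < 0:
        tau2 = 0.0
    wstar = [1.0 / (s * s + tau2) for s in ses]
    sws = sum(wstar)
    beta_random = sum(w * b for w, b in zip(wstar, betas)) / sws
    se_random = 1.0 / math.sqrt(sws)
    i2 = 0.0 if q <= 0 else max(0.0, (q - (k - 1)) / q) * 100.0
    return {
        "beta_fixed": beta_fixed,
        "se_fixed": 1.0 / math.sqrt(sw),
        "q": q,
        "tau2": tau2,
        "beta_random": beta_random,
        "se_random": se_random,
        "i2": i2,
        "ci_lower": math.exp(beta_random - 1.96 * se_random),
        "ci_upper": math.exp(beta_random + 1.96 * se_random),
    }


def hwe_exact_reference(n_ee: int, n_eo: int, n_oo: int) -> float:
    """Exact HWE p by full enumeration with rational arithmetic.

    Conditional distribution of the heterozygote count given the allele
    counts; the p-value sums all outcomes no more probable than the observed.
    """
    n = n_ee + n_eo + n_oo
    n_e = 2 * n_ee + n_eo
    rare = min(n_e, 2 * n - n_e)
    if rare == 0:
        return 1.0

    def prob(het: int) -> Fraction:
        hom_rare = (rare - het) // 2
        hom_common = n - het - hom_rare
        num = (
            math.factorial(n)
            * 2**het
            * math.factorial(rare)
            * math.factorial(2 * n - rare)
        )
        den = (
            math.factorial(hom_rare)
            * math.factorial(het)
            * math.factorial(hom_common)
            * math.factorial(2 * n)
        )
        return Fraction(num, den)

    probs = {h: prob(h) for h in range(rare % 2, rare + 1, 2)}
    observed = probs[n_eo]
    return float(min(Fraction(1), sum(p for p in probs.values() if p <= observed)))


def hwe_chi2_exact_reference(n_ee: int, n_eo: int, n_oo: int) -> float:
    """Exact distribution of the HWE chi-square statistic by full enumeration.

    Enumerates every genotype triple of the same total under a multinomial at
    the observed allele frequency and sums the probability of outcomes with a
    statistic at least as large as the observed one.  This is the exact
    counterpart of the asymptotic chi-square p (statistic-ordered), unlike
    the probability-ordered conditional exact test.
    """
    n = n_ee + n_eo + n_oo
    n_e = 2 * n_ee + n_eo
    p = n_e / (2 * n)
    if p in (0.0, 1.0):
        return 1.0
    q = 1.0 - p
    probs = (p * p, 2 * p * q, q * q)

    def stat(ee: int, eo: int, oo: int) -> float:
        ne = 2 * ee + eo
        if ne == 0 or ne == 2 * n:
            return 0.0
        ph = ne / (2 * n)
        qh = 1.0 - ph
        expected = (n * ph * ph, 2 * n * ph * qh, n * qh * qh)
        return sum(
            (o - e) ** 2 / e for o, e in zip((ee, eo, oo), expected)
        )

    observed = stat(n_ee, n_eo, n_oo)
    lf = [math.lgamma(i + 1) for i in range(n + 1)]
    lpr = [math.log(x) for x in probs]
    tail = 0.0
    for a in range(n + 1):
        for b in range(n + 1 - a):
            c = n - a - b
            if stat(a, b, c) >= observed - 1e-9:
                lp = (
                    lf[n] - lf[a] - lf[b] - lf[c]
                    + a * lpr[0] + b * lpr[1] + c * lpr[2]
                )
                tail += math.exp(lp)
    return min(1.0, tail)


def overlap_pairs_reference(
    records: Sequence[Tuple[str, int, str]], window: int
) -> Set[Tuple[int, int]]:
    """All-pairs O(n^2) proximity links between (chrom, pos, study) records.

    Returns index pairs (i < j) that share a chromosome, differ in study, and
    lie within the inclusive window.
    """
    links = set()
    for i in range(len(records)):
        for j in range(i + 1, len(records)):
            ci, pi, si = records[i]
            cj, pj, sj = records[j]
            if ci == cj and si != sj and abs(pi - pj) <= window:
                links.add((i, j))
    return links


def components_reference(n: int, links: Set[Tuple[int, int]]) -> List[Set[int]]:
    """Connected components by repeated flood fill over the link set."""
    adjacency: Dict[int, Set[int]] = {i: set() for i in range(n)}
    for i, j in links:
        adjacency[i].add(j)
        adjacency[j].add(i)
    seen: Set[int] = set()
    comps = []
    for start in range(n):
        if start in seen:
            continue
        stack, comp = [start], set()
        while stack:
            node = stack.pop()
            if node in comp:
                continue
            comp.add(node)
            stack.extend(adjacency[node] - comp)
        seen |= comp
        comps.append(comp)
    return comps
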