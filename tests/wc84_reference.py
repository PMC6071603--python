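"""Independent reference implementation of the WC84 variance components.

Deliberately coded from the ANOVA mean-squares formulation (MSP: among
populations, MSI: among individuals within populations, MSG: between gametes
within individuals) with plain Python loops, as a cross-check on the
package's vectorised algebraic form:

    a = (MSP - MSI) / (2 * n_c)
    b = (MSI - MSG) / 2
    c = MSG
"""

from math import fsum


def wc84_components(pop_genotypes):
    """(a, b, c) for one biallelic site.

    ``pop_genotypes``: one list of diploid ALT counts (0/1/2) per population,
    missing genotypes already removed.  Every population must be non-empty
    and at least one individual beyond the population count is needed overall.
    """
    r = len(pop_genotypes)
    if r < 2:
        raise ValueError("need at least 2 populations")
    n = [len(g) for g in pop_genotypes]
    if any(ni == 0 for ni in n):
        raise ValueError("empty population")
    nsum = sum(n)
    if nsum <= r:
        raise ValueError("need more individuals than populations")

    p = [fsum(g) / (2.0 * ni) for g, ni in zip(pop_genotypes, n)]
    h = [sum(1 for x in g if x == 1) / ni for g, ni in zip(pop_genotypes, n)]

    n_c = (nsum - fsum(ni * ni for ni in n) / nsum) / (r - 1)
    pbar = fsum(ni * pi for ni, pi in zip(n, p)) / nsum

    msp = fsum(2.0 * ni * (pi - pbar) ** 2 for ni, pi in zip(n, p)) / (r - 1)
    msi = fsum(
        2.0 * ni * pi * (1.0 - pi) - ni * hi / 2.0
        for ni, pi, hi in zip(n, p, h)
    ) / (nsum - r)
    msg = fsum(ni * hi for ni, hi in zip(n, h)) / (2.0 * nsum)

    a = (msp - msi) / (2.0 * n_c)
    b = (msi - msg) / 2.0
    c = msg
    return a, b, c
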