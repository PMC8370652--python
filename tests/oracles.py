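"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written from scratch (no imports from the
package under test) so the two routes can disagree.
"""

from itertools import product

# Independent bacterial codon table, encoded via the classic TCAG layout.
_BASE_ORDER = "TCAG"
_AA_STRING = (
    "FFLLSSSSYY**CC*W"
    "LLLLPPPPHHQQRRRR"
    "IIIMTTTTNNKKSSRR"
    "VVVVAAAADDEEGGGG"
)

ORACLE_CODON_TABLE = {}
for _i, (_a, _b, _c) in enumerate(product(_BASE_ORDER, repeat=3)):
    ORACLE_CODON_TABLE[_a + _b + _c] = _AA_STRING[_i]

ORACLE_STOPS = {c for c, aa in ORACLE_CODON_TABLE.items() if aa == "*"}
ORACLE_STARTS = {"ATG", "GTG", "TTG"}


def oracle_translate(cds: str, start_as_met: bool = True) -> str:
    aas = [ORACLE_CODON_TABLE[cds[i : i + 3]] for i in range(0, len(cds), 3)]
    if start_as_met and cds[:3] in ORACLE_STARTS:
        aas[0] = "M"
    return "".join(aas)


def all_point_mutants(cds: str):
    """(position 1-based, ref, alt, mutant_cds) for every single-nt substitution."""
    for i, ref in enumerate(cds):
        for alt in "ACGT":
            if alt == ref:
                continue
            yield i + 1, ref, alt, cds[:i] + alt + cds[i + 1 :]


def oracle_stop_gain_count(cds: str) -> int:
    """Brute force: substitutions in interior codons whose new codon is a stop."""
    n_codons = len(cds) // 3
    total = 0
    for pos, _ref, _alt, mutant in all_point_mutants(cds):
        codon_index = (pos - 1) // 3 + 1
        if codon_index in (1, n_codons):
            continue
        a = 3 * (codon_index - 1)
        if mutant[a : a + 3] in ORACLE_STOPS:
            total += 1
    return total


def oracle_missense_count(cds: str, residues: set[int]) -> int:
    """Brute force over full-CDS mutants: non-synonymous, non-nonsense changes
    whose affected codon lies in ``residues``."""
    wild = oracle_translate(cds, start_as_met=False)
    total = 0
    for pos, _ref, _alt, mutant in all_point_mutants(cds):
        codon_index = (pos - 1) // 3 + 1
        if codon_index not in residues:
            continue
        mut_prot = oracle_translate(mutant, start_as_met=False)
        if mut_prot[codon_index - 1] not in (wild[codon_index - 1], "*"):
            total += 1
    return total


def oracle_classify_substitution(cds: str, pos: int, alt: str) -> str:
    """Class of a single-nt substitution by translating the full mutant CDS."""
    mutant = cds[: pos - 1] + alt + cds[pos:]
    wild_prot = oracle_translate(cds)
    mut_prot = oracle_translate(mutant)
    codon_index = (pos - 1) // 3 + 1
    old_aa, new_aa = wild_prot[codon_index - 1], mut_prot[codon_index - 1]
    if new_aa == old_aa:
        return "synonymous"
    if new_aa == "*":
        return "nonsense"
    return "missense"


def oracle_direct_repeats(seq: str, min_len: int, max_del: int):
    """All maximal repeat pairs by O(n^2) scanning: (left, right, length) 1-based."""
    n = len(seq)
    out = []
    for i in range(n):
        for j in range(i + 1, min(i + max_del + 1, n)):
            # maximal means not extendable left
            if i > 0 and j > 0 and seq[i - 1] == seq[j - 1]:
                continue
            k = 0
            while j + k < n and seq[i + k] == seq[j + k]:
                k += 1
            if k >= min_len:
                out.append((i + 1, j + 1, k))
    return sorted(out)


def oracle_frameshift_weight(seq: str, h: float, min_run: int = 4) -> float:
    """Sum of per-site +-1 indel weights with homopolymer runs >= min_run weighted h."""
    total = 0.0
    i = 0
    while i < len(seq):
        j = i
        while j < len(seq) and seq[j] == seq[i]:
            j += 1
        run = j - i
        total += run * (h if run >= min_run else 1.0)
        i = j
    return total


def oracle_ws_output(components, states, deleted=False):
    """Independent re-statement of the pathway logic.

    ``components``: list of (name, role, polar_onto_dgc) tuples.
    """
    if deleted:
        return "none"
    get = lambda name: states.get(name, "wildtype")
    dgc = next(name for name, role, _ in components if role == "dgc")
    if get(dgc) in ("lof", "lof_frameshift", "absent"):
        return "none"
    for name, _role, polar in components:
        if polar and get(name) in ("lof_frameshift", "absent"):
            return "none"
    if get(dgc) == "activating":
        return "high"
    triggers = False
    for name, role, _polar in components:
        st = get(name)
        if role == "negative_regulator" and st in ("lof", "lof_frameshift", "absent"):
            triggers = True
        if role == "interacting" and st == "activating":
            triggers = True
    return "high" if triggers else "basal"


def oracle_multinomial_p(observed, probs):
    """Exact multinomial test by full enumeration with factorials."""
    from math import factorial

    n = sum(observed)
    k = len(observed)

    def pmf(counts):
        coef = factorial(n)
        p = 1.0
        for c, pr in zip(counts, probs):
            coef //= factorial(c)
            p *= pr**c
        return coef * p

    def compositions(total, parts):
        if parts == 1:
            yield (total,)
            return
        for first in range(total + 1):
            for rest in compositions(total - first, parts - 1):
                yield (first,) + rest

    p_obs = pmf(tuple(observed))
    return sum(
        pmf(c) for c in compositions(n, k) if pmf(c) <= p_obs * (1 + 1e-9)
    )
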