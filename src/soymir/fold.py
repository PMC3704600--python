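"""Deterministic RNA secondary-structure backend for hairpin evaluation.

The internal model is a simplified nearest-neighbour scheme chosen so that
its minimum is computable exactly and its optimum reproducible:

* allowed pairs: Watson-Crick (A:U, G:C) and G:U wobble,
* minimum hairpin loop of 3 unpaired bases,
* energy of a structure = +3 kcal/mol per hairpin loop (a closing pair whose
  interior is completely unpaired), plus, for every pair (i, j) whose inner
  neighbour (i+1, j-1) is also paired, a stacking bonus of -2 kcal/mol when
  (i, j) is Watson-Crick and -1 kcal/mol when it is a G:U pair.

Interior loops, bulges and multiloops carry no penalty; the model is a
base-pair maximization with stacking, not a thermodynamic ensemble, but a
perfect n-bp stem scores 3 - 2(n-1) and random sequence scores far less
negatively, which is all hairpin screening requires.  An external
thermodynamic folder (RNAfold) can be plugged in through ``backend=`` for
production use; all bundled analyses use the internal backend.

Tie-breaking is deterministic: when several structures share the optimum the
traceback pairs the 5'-most base first and prefers stacked continuations.
"""

from __future__ import annotations

import subprocess


import numpy as np

from soymir.seqs import to_dna, to_rna

MIN_LOOP = 3
HAIRPIN_INIT = 3.0
STACK_WC = -2.0
STACK_GU = -1.0

_PAIRS_WC = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
_PAIRS_GU = {("G", "T"), ("T", "G")}


def _check(seq: str) -> str:
    s = to_dna(seq)
    if not s or set(s) - set("ACGT"):
        raise ValueError("sequence must contain only A, C, G, U/T")
    return s


def pair_matrices(seq: str) -> tuple[np.ndarray, np.ndarray]:
    """(pairable, stack bonus) matrices for a DNA-alphabet sequence."""
    n = len(seq)
    ok = np.zeros((n, n), dtype=bool)
    bonus = np.zeros((n, n))
    for i in range(n):
        for j in range(i + MIN_LOOP + 1, n):
            p = (seq[i], seq[j])
            if p in _PAIRS_WC:
                ok[i, j] = True
                bonus[i, j] = STACK_WC
            elif p in _PAIRS_GU:
                ok[i, j] = True
                bonus[i, j] = STACK_GU
    return ok, bonus


def structure_energy(seq: str, pairs: set[tuple[int, int]]) -> float:
    """Energy of an explicit structure under the internal model.

    ``pairs`` are 0-based (i, j) with i < j.  Used both by the traceback
    self-check and by exhaustive-enumeration oracles.
    """
    s = _check(seq)
    e = 0.0
    for i, j in pairs:
        if not (j - i > MIN_LOOP):
            raise ValueError(f"loop shorter than {MIN_LOOP}: {(i, j)}")
        if any(i < k < l < j for k, l in pairs if (k, l) != (i, j)):
            pass  # pair closes an internal element
        else:
            e += HAIRPIN_INIT
        if (i + 1, j - 1) in pairs:
            p = (s[i], s[j])
            e += STACK_WC if p in _PAIRS_WC else STACK_GU
    return e


def pairs_to_dotbracket(n: int, pairs: set[tuple[int, int]]) -> str:
    db = ["."] * n
    for i, j in pairs:
        db[i] = "("
        db[j] = ")"
    return "".join(db)


def dotbracket_to_pairs(db: str) -> set[tuple[int, int]]:
    stack: list[int] = []
    pairs = set()
    for i, c in enumerate(db):
        if c == "(":
            stack.append(i)
        elif c == ")":
            pairs.add((stack.pop(), i))
    if stack:
        raise ValueError("unbalanced dot-bracket")
    return pairs


def fold(seq: str, backend: str = "internal") -> tuple[str, float]:
    """Fold a sequence; returns (dot-bracket structure, energy kcal/mol)."""
    if backend == "internal":
        return _fold_internal(seq)
    if backend == "rnafold":
        return _fold_rnafold(seq)
    raise ValueError(f"unknown backend {backend!r}")


def _fold_internal(seq: str) -> tuple[str, float]:
    s = _check(seq)
    n = len(s)
    if n > 400:
        raise ValueError("internal backend limited to 400 nt windows")
    ok, bonus = pair_matrices(s)
    INF = np.inf
    # E[i, j]: min energy on i..j (0 = empty structure); extra row so that
    # E[j+1, j] == 0 reads naturally.  E1 requires at least one pair.
    E = np.zeros((n + 1, n))
    E1 = np.full((n + 1, n), INF)
    Ep = np.full((n, n), INF)
    for d in range(MIN_LOOP + 1, n):
        for i in range(n - d):
            j = i + d
            if ok[i, j]:
                best = HAIRPIN_INIT
                if d >= MIN_LOOP + 3:
                    if ok[i + 1, j - 1] and Ep[i + 1, j - 1] < INF:
                        best = min(best, Ep[i + 1, j - 1] + bonus[i, j])
                    if E1[i + 1, j - 1] < INF:
                        best = min(best, E1[i + 1, j - 1])
                Ep[i, j] = best
            lo = i + MIN_LOOP + 1
            cand = Ep[i, lo : j + 1] + E[lo + 1 : j + 2, j]
            m = cand.min() if cand.size else INF
            E1[i, j] = min(E1[i + 1, j], m)
            E[i, j] = min(E[i + 1, j], m)
    mfe = float(E[0, n - 1]) if n else 0.0
    pairs = _traceback(s, ok, bonus, E, E1, Ep)
    assert structure_energy(s, pairs) == mfe if pairs else mfe == 0.0
    return pairs_to_dotbracket(n, pairs), mfe


def _traceback(s, ok, bonus, E, E1, Ep) -> set[tuple[int, int]]:
    n = len(s)
    pairs: set[tuple[int, int]] = set()
    stack: list[tuple[int, int, str]] = [(0, n - 1, "E")]
    while stack:
        i, j, state = stack.pop()
        if i >= j or j - i <= MIN_LOOP:
            continue
        if state in ("E", "E1"):
            table = E if state == "E" else E1
            target = table[i, j]
            if state == "E" and target == 0.0 and E1[i, j] > 0.0:
                continue  # empty structure is optimal
            # 5'-most pairing first: smallest k that achieves the optimum
            found = False
            for k in range(i + MIN_LOOP + 1, j + 1):
                if ok[i, k] and Ep[i, k] + E[k + 1, j] == target:
                    stack.append((i, k, "P"))
                    stack.append((k + 1, j, "E"))
                    found = True
                    break
            if not found:
                stack.append((i + 1, j, state))
        else:  # (i, j) paired
            pairs.add((i, j))
            v = Ep[i, j]
            if (
                j - i >= MIN_LOOP + 3
                and ok[i + 1, j - 1]
                and Ep[i + 1, j - 1] < np.inf
                and Ep[i + 1, j - 1] + bonus[i, j] == v
            ):
                stack.append((i + 1, j - 1, "P"))
            elif j - i >= MIN_LOOP + 3 and E1[i + 1, j - 1] == v:
                stack.append((i + 1, j - 1, "E1"))
            # else: hairpin loop, nothing inside
    return pairs


def _fold_rnafold(seq: str) -> tuple[str, float]:
    """External thermodynamic backend via the RNAfold executable."""
    rna = to_rna(_check(seq))
    out = subprocess.run(
        ["RNAfold", "--noPS"], input=rna + "\n", capture_output=True, text=True, check=True
    ).stdout.splitlines()
    struct_line = out[1]
    db = struct_line.split()[0]
    mfe = float(struct_line.rsplit("(", 1)[1].rstrip(")").strip())
    return db, mfe
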