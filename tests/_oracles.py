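"""Naive, loop-based reference implementations used as independent oracles.

These deliberately avoid the package's internals and any vectorization: pair
matching by explicit stack walk, window tallies by plain loops, metrics by
direct formula transcription. They exist so the production code can be checked
against a second, independently written path.
"""

from __future__ import annotations

import math

NTS = "ACGU"
PATTERNS = ["(((", "((.", "(..", "(.(", ".((", ".(.", "..(", "..."]


def pair_map(db: str) -> dict[int, int]:
    """1-based pair table by explicit stack walk."""
    stack, table = [], {}
    for k, ch in enumerate(db, start=1):
        if ch == "(":
            stack.append(k)
        elif ch == ")":
            i = stack.pop()
            table[i] = k
            table[k] = i
    assert not stack
    return table


def stem_runs(db: str, min_len: int = 4) -> int:
    """Count maximal stacked-pair runs of length >= min_len by enumeration."""
    table = pair_map(db)
    openers = sorted(i for i in table if i < table[i])
    runs, current = [], []
    for i in openers:
        if current and i == current[-1] + 1 and table[i] == table[current[-1]] - 1:
            current.append(i)
        else:
            if current:
                runs.append(len(current))
            current = [i]
    if current:
        runs.append(len(current))
    return sum(1 for r in runs if r >= min_len)


def hairpin_loops(db: str) -> list[tuple[int, int]]:
    """All (start, end) unpaired runs enclosed by a matching pair."""
    table = pair_map(db)
    loops = []
    k = 0
    n = len(db)
    while k < n:
        if db[k] == ".":
            start = k
            while k < n and db[k] == ".":
                k += 1
            end = k - 1
            if (
                start - 1 >= 0
                and end + 1 < n
                and db[start - 1] == "("
                and db[end + 1] == ")"
                and table.get(start) == end + 2  # 1-based: opener start pairs closer end+2
            ):
                loops.append((start + 1, end + 1))
        else:
            k += 1
    return loops


def triplet_frequencies(seq: str, db: str) -> dict[str, float]:
    flat = "".join("(" if c in "()" else "." for c in db)
    counts = {f"{n}{p}": 0 for n in NTS for p in PATTERNS}
    for i in range(len(seq) - 2):
        counts[seq[i + 1] + flat[i : i + 3]] += 1
    return {f"triplet_{k}": v / (len(seq) - 2) for k, v in counts.items()}


def composition(seq: str) -> dict[str, float]:
    L = len(seq)
    out = {}
    for n in NTS:
        c = sum(1 for ch in seq if ch == n)
        out[f"count_{n}"] = c
        out[f"pct_{n}"] = c * 100.0 / L
    for a in NTS:
        for b in NTS:
            c = 0
            for i in range(L - 1):
                if seq[i] == a and seq[i + 1] == b:
                    c += 1
            out[f"count_{a}{b}"] = c
            out[f"pct_{a}{b}"] = c * 100.0 / (L - 1)
    gc = out["count_G"] + out["count_C"]
    au = out["count_A"] + out["count_U"]
    out["count_G+C"] = gc
    out["count_A+U"] = au
    out["pct_G+C"] = gc * 100.0 / L
    out["pct_A+U"] = au * 100.0 / L
    out["length"] = float(L)
    return out


def structural_thermo(seq: str, db: str, mfe: float) -> dict[str, float]:
    L = len(seq)
    tot_bp = sum(1 for c in db if c == "(")
    n_stems = stem_runs(db)
    loops = hairpin_loops(db)
    n_loops = len(loops)
    loop_len = sum(e - s + 1 for s, e in loops)
    dG = mfe / L
    pct_gc = (sum(1 for c in seq if c in "GC")) * 100.0 / L

    def div(a, b):
        return a / b if b else 0.0

    return {
        "tot_bp": float(tot_bp),
        "n_stems": float(n_stems),
        "n_loops": float(n_loops),
        "loop_length": float(loop_len),
        "dP": tot_bp / L,
        "avg_bp": div(tot_bp, n_stems),
        "MFE": mfe,
        "dG": dG,
        "MFE1": div(dG, pct_gc),
        "MFE2": div(dG, n_stems),
        "MFE3": div(dG, n_loops),
        "MFE4": div(dG, tot_bp),
    }


def ensemble(pair_probs, L: int) -> dict[str, float]:
    q = 0.0
    dd = 0.0
    n = len(pair_probs)
    for i in range(n):
        for j in range(i + 1, n):
            p = float(pair_probs[i][j])
            if p > 0:
                q -= p * math.log2(p)
            dd += p * (1.0 - p)
    return {"Q": q, "dQ": q / L, "dD": dd / L}


def full_descriptor(seq: str, db: str, mfe: float, pair_probs) -> dict[str, float]:
    out: dict[str, float] = {}
    out.update(triplet_frequencies(seq, db))
    out.update(composition(seq))
    out.update(structural_thermo(seq, db, mfe))
    out.update(ensemble(pair_probs, len(seq)))
    out["zD"] = 0.0
    return out


def confusion_metrics(tp: int, tn: int, fp: int, fn: int) -> dict[str, float]:
    """Direct formula transcription, guarded divisions."""
    def div(a, b):
        return a / b if b else 0.0

    sn = div(tp, tp + fn)
    sp = div(tn, tn + fp)
    p = div(tp, tp + fp)
    den = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    return {
        "acc": div(tp + tn, tp + tn + fp + fn),
        "sn": sn,
        "sp": sp,
        "precision": p,
        "f1": div(2 * sn * p, sn + p),
        "mcc": (tp * tn - fp * fn) / den if den else 0.0,
    }


def random_balanced_dotbracket(rng, n: int) -> str:
    """A random balanced dot-bracket string of length n (non-crossing)."""
    out = []
    open_count = 0
    for k in range(n):
        remaining = n - k
        choices = ["."]
        if remaining >= open_count + 2:
            choices.append("(")
        if open_count > 0:
            choices.append(")")
        # force closure when needed
        if open_count == remaining:
            ch = ")"
        else:
            ch = choices[rng.integers(len(choices))]
        if ch == "(":
            open_count += 1
        elif ch == ")":
            open_count -= 1
        out.append(ch)
    return "".join(out)
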