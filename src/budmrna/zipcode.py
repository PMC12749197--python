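"""She2-type zipcode discovery and synonymous destruction.

The search proceeds in two stages, mirroring how bud-localization elements of
the *ASH1* E3 class are defined:

1. a lenient combinatorial scan for two nested inverted-repeat stems (>= 4 bp
   each) framing an asymmetric bulge, carrying a CGA trinucleotide and an
   isolated, unpaired cytosine a fixed number of nucleotides away (default 6);
2. a structure filter that folds an 80-nt window centred on each candidate at
   28 degC with and without forcing the candidate stems, and keeps candidates
   whose stems survive in the unconstrained MFE structure and whose
   constrained fold costs no more than 20 % extra free energy.

Pairing allows G.U wobble by default: the minimal CLB2 element's outer stem
contains a G.U pair and would be invisible to a strict Watson-Crick scan.
Overlapping surviving candidates are merged into a single hit reported with
the union span.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

from .codons import SYNONYMS, codon_usage_frequency, relative_adaptiveness
from .transcript import Transcript, as_rna

try:  # ViennaRNA python bindings
    import RNA as _vienna
except ImportError:  # pragma: no cover - folding engine is a hard runtime dep
    _vienna = None

WATSON_CRICK = frozenset({("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")})
WOBBLE = frozenset({("G", "U"), ("U", "G")})


@dataclass(frozen=True)
class ScanRules:
    """Configuration of the combinatorial candidate scan."""

    min_stem: int = 4
    max_span: int = 60
    allow_gu: bool = True
    cga_c_spacing: tuple[int, ...] = (6,)
    require_cga: bool = True

    @property
    def pair_set(self) -> frozenset:
        return WATSON_CRICK | WOBBLE if self.allow_gu else WATSON_CRICK


@dataclass(frozen=True)
class Stem:
    """An inverted repeat: left arm [left_start, left_end] pairs antiparallel
    with right arm [right_start, right_end]; 1-based inclusive coordinates."""

    left_start: int
    left_end: int
    right_start: int
    right_end: int

    @property
    def length(self) -> int:
        return self.left_end - self.left_start + 1

    def base_pairs(self) -> list[tuple[int, int]]:
        return [(self.left_start + t, self.right_end - t) for t in range(self.length)]

    def positions(self) -> set[int]:
        return set(range(self.left_start, self.left_end + 1)) | set(
            range(self.right_start, self.right_end + 1)
        )


@dataclass(frozen=True)
class ZipCodeCandidate:
    outer: Stem
    inner: Stem
    bulge_left: int
    bulge_right: int
    cga_pos: int
    lone_c_pos: int
    span: tuple[int, int]  # 1-based inclusive

    @property
    def stems(self) -> tuple[Stem, Stem]:
        return (self.outer, self.inner)


@dataclass(frozen=True)
class FoldResult:
    window: tuple[int, int]  # 1-based inclusive, absolute transcript coords
    structure: str
    dG: float  # kcal/mol
    constrained: bool
    temperature: float
    ok: bool = True


@dataclass(frozen=True)
class ZipCodeHit:
    candidate: ZipCodeCandidate
    fold_free: FoldResult
    fold_constrained: FoldResult
    stem_in_mfe: bool
    dG_ratio_ok: bool
    span: tuple[int, int]  # union span after merging, absolute 1-based
    cds_span: tuple[int, int] | None  # CDS-relative (+1 = A of ATG) if inside CDS
    frame: str  # "cds", "5utr", "3utr" or "mixed"
    n_merged: int = 1


# ---------------------------------------------------------------------------
# stage 1: combinatorial scan


def _enumerate_stems(seq: str, rules: ScanRules) -> list[tuple[int, int, int]]:
    """All (i, j, k) 0-based: seq[i:i+k] pairs antiparallel with seq[j-k+1:j+1],
    k >= min_stem, overall extent j - i + 1 <= max_span."""
    pairs = rules.pair_set
    n = len(seq)
    out = []
    for i in range(n):
        j_hi = min(n, i + rules.max_span)
        for j in range(i + 2 * rules.min_stem - 1, j_hi):
            k = 0
            while i + k < j - k and (seq[i + k], seq[j - k]) in pairs:
                k += 1
                if k >= rules.min_stem:
                    out.append((i, j, k))
    return out


def _isolated_cytosines(seq: str) -> list[int]:
    return [
        q
        for q, ch in enumerate(seq)
        if ch == "C"
        and (q == 0 or seq[q - 1] != "C")
        and (q == len(seq) - 1 or seq[q + 1] != "C")
    ]


def scan_candidates(transcript: Transcript | str, rules: ScanRules | None = None) -> list[ZipCodeCandidate]:
    """Enumerate every nested-stem/bulge/CGA candidate on the transcript.

    Returns candidates in deterministic order (ascending span start, then
    span end, then arm coordinates).
    """
    rules = rules or ScanRules()
    seq = as_rna(transcript.seq if isinstance(transcript, Transcript) else transcript)
    if not seq:
        return []
    stems = _enumerate_stems(seq, rules)
    cga_starts = [p for p in range(len(seq) - 2) if seq[p : p + 3] == "CGA"]
    lone_cs = _isolated_cytosines(seq)
    spacing = set(rules.cga_c_spacing)

    # index inner-stem candidates by left-arm start for the nesting sweep
    out: list[ZipCodeCandidate] = []
    seen = set()
    for (i, j, k1) in stems:
        loop_lo, loop_hi = i + k1, j - k1  # 0-based bounds of the outer loop
        for (a, b, k2) in stems:
            if a < loop_lo or b > loop_hi:
                continue
            if (a, b, k2) == (i, j, k1):
                continue
            bl = a - loop_lo
            br = loop_hi - b
            if bl + br < 1 or abs(bl - br) < 1:
                continue
            arm_pos = (
                set(range(i, i + k1))
                | set(range(j - k1 + 1, j + 1))
                | set(range(a, a + k2))
                | set(range(b - k2 + 1, b + 1))
            )
            if rules.require_cga:
                motif = None
                for p in cga_starts:
                    if p < i or p + 2 > j or {p, p + 1, p + 2} & arm_pos:
                        continue
                    for q in lone_cs:
                        if q < i or q > j or q in arm_pos:
                            continue
                        if abs(q - p) in spacing:
                            motif = (p, q)
                            break
                    if motif:
                        break
                if motif is None:
                    continue
                cga, lone = motif
            else:
                cga, lone = -1, -1
            key = (i, j, k1, a, b, k2, cga, lone)
            if key in seen:
                continue
            seen.add(key)
            out.append(
                ZipCodeCandidate(
                    outer=Stem(i + 1, i + k1, j - k1 + 2, j + 1),
                    inner=Stem(a + 1, a + k2, b - k2 + 2, b + 1),
                    bulge_left=bl,
                    bulge_right=br,
                    cga_pos=cga + 1,
                    lone_c_pos=lone + 1,
                    span=(i + 1, j + 1),
                )
            )
    out.sort(
        key=lambda c: (c.span[0], c.span[1], c.outer.left_end, c.inner.left_start, c.inner.right_end)
    )
    return out


# ---------------------------------------------------------------------------
# stage 2: folding filter


def _require_vienna():
    if _vienna is None:
        raise RuntimeError("the ViennaRNA python bindings (module 'RNA') are required for folding")


def _structure_pairs(structure: str) -> set[tuple[int, int]]:
    """Base pairs of a dot-bracket string, 1-based (i < j)."""
    stack: list[int] = []
    pairs = set()
    for idx, ch in enumerate(structure, start=1):
        if ch == "(":
            stack.append(idx)
        elif ch == ")":
            pairs.add((stack.pop(), idx))
    return pairs


def fold_window(
    transcript: Transcript | str,
    center: int,
    width: int = 80,
    temperature: float = 28.0,
    constraint: list[tuple[int, int]] | None = None,
) -> FoldResult:
    """MFE-fold a window of ``width`` nt centred on ``center`` (1-based).

    The window is clipped (not shifted) at the sequence ends.  ``constraint``
    is a list of absolute base pairs forced into the structure; an infeasible
    constraint yields ``ok=False`` rather than an exception.
    """
    _require_vienna()
    seq = as_rna(transcript.seq if isinstance(transcript, Transcript) else transcript)
    n = len(seq)
    if not (1 <= center <= n):
        raise ValueError(f"center {center} outside sequence of length {n}")
    lo = max(1, center - (width - 1) // 2)
    hi = min(n, center + width // 2)
    frag = seq[lo - 1 : hi]

    md = _vienna.md()
    md.temperature = temperature
    fc = _vienna.fold_compound(frag, md)
    if constraint:
        for (bi, bj) in constraint:
            if not (lo <= bi <= hi and lo <= bj <= hi):
                raise ValueError(f"constraint pair ({bi},{bj}) outside window {lo}..{hi}")
            fc.hc_add_bp(
                bi - lo + 1,
                bj - lo + 1,
                _vienna.CONSTRAINT_CONTEXT_ALL_LOOPS | _vienna.CONSTRAINT_CONTEXT_ENFORCE,
            )
    try:
        structure, dG = fc.mfe()
    except Exception:
        return FoldResult((lo, hi), "." * len(frag), 0.0, constraint is not None, temperature, ok=False)
    ok = True
    if constraint:
        got = _structure_pairs(structure)
        want = {(bi - lo + 1, bj - lo + 1) for (bi, bj) in constraint}
        ok = want <= got
    return FoldResult((lo, hi), structure, float(dG), constraint is not None, temperature, ok=ok)


def filter_candidate(
    candidate: ZipCodeCandidate,
    fold_free: FoldResult,
    fold_constrained: FoldResult,
    tolerance: float = 0.20,
) -> tuple[bool, bool]:
    """(stem_in_mfe, dG_ratio_ok) verdict pair.

    ``stem_in_mfe``: every base pair of at least one of the two stems appears
    in the unconstrained MFE structure.  ``dG_ratio_ok``: the constrained fold
    free energy differs from the unconstrained MFE by at most ``tolerance``
    of its magnitude (both defined as true/false on a 0-energy fold).
    """
    lo = fold_free.window[0]
    mfe_pairs = _structure_pairs(fold_free.structure)
    stem_in_mfe = False
    for stem in candidate.stems:
        local = {(bi - lo + 1, bj - lo + 1) for (bi, bj) in stem.base_pairs()}
        if local <= mfe_pairs:
            stem_in_mfe = True
            break
    if not fold_constrained.ok:
        return stem_in_mfe, False
    if fold_free.dG == 0.0:
        dg_ok = fold_constrained.dG == 0.0
    else:
        dg_ok = abs(fold_constrained.dG - fold_free.dG) <= tolerance * abs(fold_free.dG)
    return stem_in_mfe, dg_ok


# ---------------------------------------------------------------------------
# composition


@dataclass(frozen=True)
class SearchConfig:
    rules: ScanRules = field(default_factory=ScanRules)
    window: int = 80
    temperature: float = 28.0
    tolerance: float = 0.20
    merge_overlapping: bool = True


def _frame_label(transcript: Transcript, span: tuple[int, int]) -> tuple[str, tuple[int, int] | None]:
    s, e = span
    if transcript.in_cds(s, e):
        return "cds", (transcript.to_cds_coords(s), transcript.to_cds_coords(e))
    if e < transcript.cds_start:
        return "5utr", None
    if s > transcript.cds_end:
        return "3utr", None
    return "mixed", None


def search_zipcodes(transcript: Transcript, config: SearchConfig | None = None) -> list[ZipCodeHit]:
    """Scan -> fold (free and constrained) -> filter -> merge.

    Hits are reported in CDS-relative coordinates when the merged span lies
    inside the CDS, otherwise with a UTR frame label.
    """
    config = config or SearchConfig()
    candidates = scan_candidates(transcript, config.rules)
    survivors: list[ZipCodeHit] = []
    for cand in candidates:
        center = (cand.span[0] + cand.span[1]) // 2
        free = fold_window(transcript, center, config.window, config.temperature)
        constraint = [bp for stem in cand.stems for bp in stem.base_pairs()]
        constrained = fold_window(transcript, center, config.window, config.temperature, constraint)
        stem_ok, dg_ok = filter_candidate(cand, free, constrained, config.tolerance)
        if stem_ok and dg_ok:
            frame, cds_span = _frame_label(transcript, cand.span)
            survivors.append(
                ZipCodeHit(cand, free, constrained, stem_ok, dg_ok, cand.span, cds_span, frame)
            )
    if not config.merge_overlapping or not survivors:
        return survivors
    # merge overlapping spans into union-span hits, keeping the first
    # (lowest-coordinate) candidate as representative
    survivors.sort(key=lambda h: h.span)
    merged: list[ZipCodeHit] = []
    for hit in survivors:
        if merged and hit.span[0] <= merged[-1].span[1]:
            prev = merged[-1]
            union = (prev.span[0], max(prev.span[1], hit.span[1]))
            frame, cds_span = _frame_label(transcript, union)
            merged[-1] = replace(prev, span=union, cds_span=cds_span, frame=frame, n_merged=prev.n_merged + 1)
        else:
            merged.append(hit)
    return merged


# ---------------------------------------------------------------------------
# synonymization


@dataclass(frozen=True)
class SynonymizationResult:
    mutant: Transcript
    n_changes: int
    protein_identical: bool
    codon_usage_before: float
    codon_usage_after: float
    residual_hits: int
    success: bool
    changed_positions: tuple[int, ...] = ()  # absolute 1-based


def _overlapping_candidates(seq_rna: str, span: tuple[int, int], rules: ScanRules) -> int:
    # any candidate overlapping the span lies within +- max_span of it, so
    # scanning a local window is exact and much cheaper on long transcripts
    lo = max(1, span[0] - rules.max_span)
    hi = min(len(seq_rna), span[1] + rules.max_span)
    window = seq_rna[lo - 1 : hi]
    n = 0
    for cand in scan_candidates(window, rules):
        s, e = cand.span[0] + lo - 1, cand.span[1] + lo - 1
        if s <= span[1] and e >= span[0]:
            n += 1
    return n


def synonymize_zipcode(
    transcript: Transcript,
    hit: ZipCodeHit | None,
    codon_table: dict[str, float] | None = None,
    max_changes: int = 12,
    config: SearchConfig | None = None,
    usage_tolerance: float = 0.10,
) -> SynonymizationResult:
    """Destroy a zipcode by greedy synonymous substitution inside its span.

    Single synonymous codon swaps within the hit-span codons are applied one
    at a time, each chosen to minimise the number of scan-stage candidates
    still overlapping the span (tie-break: fewest base changes, then highest
    codon adaptiveness).  Eliminating every scan candidate guarantees the
    full search reports no hit there.  Fails explicitly if ``max_changes``
    base substitutions do not suffice.
    """
    config = config or SearchConfig()
    usage_before = codon_usage_frequency(transcript.cds, codon_table)
    if hit is None:
        return SynonymizationResult(
            transcript, 0, True, usage_before, usage_before, 0, True
        )
    s, e = hit.span
    if not transcript.in_cds(s, e):
        raise ValueError("hit span must lie within the CDS to synonymize")
    w = relative_adaptiveness(codon_table)
    rules = config.rules
    seq = list(transcript.rna)
    cds0 = transcript.cds_start - 1  # 0-based index of A of ATG
    first_codon = (s - 1 - cds0) // 3
    last_codon = (e - 1 - cds0) // 3
    protein = transcript.protein

    changed: set[int] = set()  # absolute 1-based positions substituted
    frozen_codons: dict[int, str] = {}  # codon idx -> chosen codon (no revisits)

    def codon_at(sq, k):
        off = cds0 + 3 * k
        return "".join(sq[off : off + 3])

    current = _overlapping_candidates("".join(seq), (s, e), rules)
    while current > 0 and len(changed) < max_changes:
        best = None
        for k in range(first_codon, last_codon + 1):
            if k in frozen_codons:
                continue
            old = codon_at(seq, k)
            aa = protein[k]
            for new in SYNONYMS.get(aa, []):
                if new == old:
                    continue
                diffs = [t for t in range(3) if new[t] != old[t]]
                if len(changed) + len(diffs) > max_changes:
                    continue
                trial = seq.copy()
                off = cds0 + 3 * k
                for t in diffs:
                    trial[off + t] = new[t]
                cnt = _overlapping_candidates("".join(trial), (s, e), rules)
                score = (cnt, len(diffs), -w.get(new, 0.0), k, new)
                if best is None or score < best[0]:
                    best = (score, k, new, diffs)
        if best is None:
            break
        (cnt, _ndiff, _negw, _k, _new), k, new, diffs = best
        if cnt >= current:
            # no move reduces the count: accept the least harmful move once,
            # but stop if even that cannot make progress within the budget
            if cnt > current:
                break
        off = cds0 + 3 * k
        for t in diffs:
            seq[off + t] = new[t]
            changed.add(off + t + 1)
        frozen_codons[k] = new
        current = cnt

    mutant = Transcript(
        id=f"{transcript.id}_zipmut",
        seq="".join(seq),
        cds_start=transcript.cds_start,
        cds_end=transcript.cds_end,
    )
    protein_identical = mutant.protein == protein
    usage_after = codon_usage_frequency(mutant.cds, codon_table)
    residual = sum(
        1 for h in search_zipcodes(mutant, config) if h.span[0] <= e and h.span[1] >= s
    )
    success = residual == 0 and protein_identical
    if success and abs(usage_after - usage_before) > usage_tolerance:
        warnings.warn(
            f"codon usage moved from {usage_before:.3f} to {usage_after:.3f} "
            f"(tolerance {usage_tolerance})"
        )
    return SynonymizationResult(
        mutant,
        len(changed),
        protein_identical,
        usage_before,
        usage_after,
        residual,
        success,
        tuple(sorted(changed)),
    )
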