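"""Motif analysis: peak-sequence extraction, random peak sampling, IUPAC
consensus scanning, empirical enrichment, one-occurrence-per-sequence EM
motif discovery, and PWM-library scanning with a core-score cutoff.

The discovery model assumes exactly one motif site per input sequence
(OOPS): the E-step places a posterior over site offsets under the current
position weight matrix against a 0-order background, the M-step re-estimates
the PWM from the expected letter counts (pseudocount 0.25).  The best of
several random restarts is returned.  No multi-width search, erasure, or
E-value calibration is attempted — site discovery on summit-centered windows
is the use case.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import GenomeAssembly, Peak, ValidationError, log

BASES = "ACGT"
_BASE_IDX = {b: i for i, b in enumerate(BASES)}

IUPAC_CODES: dict[str, frozenset] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"), "W": frozenset("AT"),
    "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"), "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def revcomp(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MotifHit:
    sequence_id: str
    offset: int
    strand: str
    matched: str


@dataclass
class PWM:
    """Column-stochastic position weight matrix over A, C, G, T."""

    probs: np.ndarray  # shape (width, 4)
    pseudocount: float = 0.25

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4 or self.probs.shape[0] < 4:
            raise ValidationError("PWM needs shape (width >= 4, 4)")
        if not np.allclose(self.probs.sum(axis=1), 1.0):
            raise ValidationError("PWM columns must sum to 1")

    @property
    def width(self) -> int:
        return self.probs.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.probs.argmax(axis=1))

    def information_content(self, background: np.ndarray | None = None) -> np.ndarray:
        """Per-position information (bits) relative to the background."""
        bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
        p = self.probs
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(p > 0, p * np.log2(p / bg), 0.0)
        return terms.sum(axis=1)


# ---------------------------------------------------------------------------
# sequence extraction and sampling
# ---------------------------------------------------------------------------

def extract_peak_sequences(peaks: list[Peak], genome: GenomeAssembly,
                           flank_bp: int = 100) -> dict[str, str]:
    """Summit-centered windows genome[summit - flank, summit + flank + 1)
    (201 bp at the default), clipped at chromosome ends, uppercase."""
    if genome.sequence is None:
        raise ValidationError("genome has no sequence")
    out: dict[str, str] = {}
    for p in peaks:
        if p.chrom not in genome.sequence:
            raise ValidationError(f"peak {p.peak_id}: unknown chromosome {p.chrom!r}")
        clen = genome.chrom_lengths[p.chrom]
        lo, hi = p.summit - flank_bp, p.summit + flank_bp + 1
        clo, chi = max(0, lo), min(clen, hi)
        if (clo, chi) != (lo, hi):
            log.info("extract_peak_sequences: window clipped for %s", p.peak_id)
        out[p.peak_id] = genome.sequence[p.chrom][clo:chi].upper()
    return out


def sample_peak_groups(peaks: list[Peak], n: int = 600, groups: int = 3,
                       seed: int = 0) -> list[list[str]]:
    """Independent uniform samples of ``n`` peak ids, each drawn without
    replacement within its group (groups may overlap each other)."""
    ids = [p.peak_id for p in peaks]
    if len(ids) < n:
        raise ValidationError(
            f"cannot sample {n} peaks from {len(ids)}; lower n to <= {len(ids)}")
    rng = np.random.default_rng(seed)
    return [[ids[i] for i in rng.choice(len(ids), size=n, replace=False)]
            for _ in range(groups)]


# ---------------------------------------------------------------------------
# IUPAC scanning
# ---------------------------------------------------------------------------

def _validate_pattern(pattern: str) -> str:
    pattern = pattern.upper()
    bad = set(pattern) - set(IUPAC_CODES)
    if not pattern or bad:
        raise ValidationError(f"invalid IUPAC pattern {pattern!r} (bad codes: {sorted(bad)})")
    return pattern


def iupac_scan(sequence: str, pattern: str, both_strands: bool = True,
               sequence_id: str = "") -> list[MotifHit]:
    """All (possibly overlapping) matches of an IUPAC consensus.

    Minus-strand hits are occurrences of the reverse complement of the
    pattern, reported at their forward-sequence offset with the forward
    substring.
    """
    pattern = _validate_pattern(pattern)
    sequence = sequence.upper()
    hits = [MotifHit(sequence_id, off, "+", sequence[off:off + len(pattern)])
            for off in _scan_offsets(sequence, pattern)]
    if both_strands:
        rc = revcomp(pattern)
        if rc != pattern:
            minus = _scan_offsets(sequence, rc)
        else:  # palindromic consensus: same offsets on both strands
            minus = [h.offset for h in hits]
        hits += [MotifHit(sequence_id, off, "-", sequence[off:off + len(pattern)])
                 for off in minus]
    return sorted(hits, key=lambda h: (h.offset, h.strand))


def _scan_offsets(sequence: str, pattern: str) -> list[int]:
    w = len(pattern)
    sets = [IUPAC_CODES[c] for c in pattern]
    return [i for i in range(len(sequence) - w + 1)
            if all(sequence[i + j] in sets[j] for j in range(w))]


def hit_bearing_fraction(seqs: dict[str, str], pattern: str,
                         both_strands: bool = True) -> float:
    if not seqs:
        return 0.0
    return float(np.mean([bool(iupac_scan(s, pattern, both_strands)) for s in seqs.values()]))


# ---------------------------------------------------------------------------
# dinucleotide shuffle and enrichment
# ---------------------------------------------------------------------------

def dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Shuffle preserving exact dinucleotide counts (random Eulerian walk
    on the letter graph, Altschul-Erickson style)."""
    seq = seq.upper()
    if len(seq) < 3:
        return seq
    edges: dict[str, list[str]] = {}
    for a, b in zip(seq, seq[1:]):
        edges.setdefault(a, []).append(b)
    # pick each non-terminal vertex's last exit uniformly, then check the
    # "last-edge tree" connects to the terminal vertex; retry until valid
    last = seq[-1]
    vertices = list(edges)
    for _ in range(1000):
        last_out = {v: edges[v][int(rng.integers(len(edges[v])))] for v in vertices if v != last}
        ok = True
        for v in last_out:
            seen, cur = {v}, v
            while cur != last and cur in last_out:
                cur = last_out[cur]
                if cur in seen:
                    break
                seen.add(cur)
            if cur != last and (cur in seen or cur not in edges):
                ok = False
                break
        if ok:
            break
    shuffled_edges = {}
    for v in vertices:
        rest = list(edges[v])
        if v != last:
            rest.remove(last_out[v])
        rng.shuffle(rest)
        shuffled_edges[v] = rest + ([last_out[v]] if v != last else [])
    out = [seq[0]]
    cur = seq[0]
    counters = {v: 0 for v in vertices}
    for _ in range(len(seq) - 1):
        nxt = shuffled_edges[cur][counters[cur]]
        counters[cur] += 1
        out.append(nxt)
        cur = nxt
    return "".join(out)


def motif_enrichment(fg_sequences: dict[str, str], pattern: str,
                     bg_sequences: dict[str, str] | None = None,
                     n_shuffles: int = 100, seed: int = 0,
                     both_strands: bool = True) -> dict:
    """Enrichment of an IUPAC consensus against a composition-matched null.

    ratio = fg hit-bearing fraction / mean background fraction; the
    empirical p is (1 + #{bg >= fg}) / (1 + n_shuffles), so the smallest
    attainable p is 1/(1 + n_shuffles).  The background is the supplied set
    (scored once per shuffle round by resampling it) or, by default,
    dinucleotide-shuffled copies of the foreground.
    """
    if not fg_sequences:
        raise ValidationError("empty foreground")
    pattern = _validate_pattern(pattern)
    rng = np.random.default_rng(seed)
    fg_frac = hit_bearing_fraction(fg_sequences, pattern, both_strands)
    bg_fracs = []
    for _ in range(n_shuffles):
        if bg_sequences is None:
            shuf = {k: dinucleotide_shuffle(s, rng) for k, s in fg_sequences.items()}
        else:
            keys = list(bg_sequences)
            pick = rng.choice(len(keys), size=len(fg_sequences), replace=True)
            shuf = {f"b{i}": bg_sequences[keys[j]] for i, j in enumerate(pick)}
        bg_fracs.append(hit_bearing_fraction(shuf, pattern, both_strands))
    bg_fracs = np.array(bg_fracs)
    mean_bg = float(bg_fracs.mean())
    ratio = fg_frac / mean_bg if mean_bg > 0 else np.inf
    p = (1 + int((bg_fracs >= fg_frac).sum())) / (1 + n_shuffles)
    return {"fg_fraction": fg_frac, "bg_fraction": mean_bg,
            "ratio": ratio, "p_value": p, "n_shuffles": n_shuffles}


# ---------------------------------------------------------------------------
# OOPS EM discovery
# ---------------------------------------------------------------------------

def _encode(seq: str) -> np.ndarray:
    return np.array([_BASE_IDX.get(c, -1) for c in seq.upper()], dtype=np.int64)


def oops_em_discover(sequences: dict[str, str] | list[str], width: int = 6,
                     seed: int = 0, max_iter: int = 200, tol: float = 1e-6,
                     n_restarts: int = 5,
                     init_pwms: list[np.ndarray] | None = None
                     ) -> tuple[PWM, str, dict]:
    """One-occurrence-per-sequence EM motif discovery.

    Returns (PWM, consensus, info) where info carries the final
    log-likelihood, its gain over the background-only model, and the
    per-sequence MAP site offsets.  The log-likelihood is non-decreasing
    across EM iterations (asserted); the best of ``n_restarts`` seeded
    restarts is returned.
    """
    seq_list = list(sequences.values()) if isinstance(sequences, dict) else list(sequences)
    if len(seq_list) < 10:
        raise ValidationError("need >= 10 sequences for discovery")
    if any(len(s) < width for s in seq_list):
        raise ValidationError(f"all sequences must be >= width {width}")
    enc = [_encode(s) for s in seq_list]
    enc = [e[e >= 0] for e in enc]  # drop Ns for counting/scanning
    if any(len(e) < width for e in enc):
        raise ValidationError("sequences too short after removing ambiguous bases")

    counts = np.zeros(4)
    for e in enc:
        counts += np.bincount(e, minlength=4)
    background = counts / counts.sum()
    log_bg = np.log(background)
    bg_ll = float(sum(log_bg[e].sum() for e in enc))

    master = np.random.default_rng(seed)
    best = None
    if init_pwms is not None:
        starts = [np.asarray(m, dtype=float) for m in init_pwms]
    else:
        starts = [None] * n_restarts
    for init in starts:
        rng = np.random.default_rng(master.integers(2 ** 31))
        pwm, ll = _em_run(enc, width, background, rng, max_iter, tol, init)
        if best is None or ll > best[1]:
            best = (pwm, ll)
    pwm, ll = best
    offsets = [int(np.argmax(_window_scores(e, np.log(pwm), log_bg, width))) for e in enc]
    result = PWM(pwm)
    info = {"log_likelihood": ll, "background_log_likelihood": bg_ll,
            "gain_bits_per_sequence": (ll - bg_ll) / np.log(2) / len(enc),
            "site_offsets": offsets, "background": background}
    return result, result.consensus, info


def _window_scores(e: np.ndarray, log_pwm: np.ndarray, log_bg: np.ndarray,
                   w: int) -> np.ndarray:
    """Log-likelihood-ratio score of the width-w window at every offset."""
    n = len(e) - w + 1
    scores = np.zeros(n)
    for j in range(w):
        scores += log_pwm[j, e[j:j + n]] - log_bg[e[j:j + n]]
    return scores


def _em_run(enc: list[np.ndarray], w: int, background: np.ndarray,
            rng: np.random.Generator, max_iter: int, tol: float,
            init: np.ndarray | None = None):
    if init is not None:
        pwm = init.copy()
    else:  # init: PWM biased toward a random seed w-mer
        seq = enc[int(rng.integers(len(enc)))]
        off = int(rng.integers(len(seq) - w + 1))
        pwm = np.full((w, 4), 0.15)
        pwm[np.arange(w), seq[off:off + w]] = 0.55
    pwm /= pwm.sum(axis=1, keepdims=True)

    log_bg = np.log(background)
    prev_obj = -np.inf
    ll = -np.inf
    for _ in range(max_iter):
        log_pwm = np.log(pwm)
        new_counts = np.full((w, 4), 0.25)  # pseudocount
        ll = 0.0
        for e in enc:
            scores = _window_scores(e, log_pwm, log_bg, w)
            m = scores.max()
            post = np.exp(scores - m)
            z = post.sum()
            post /= z
            # per-sequence log-likelihood: uniform site prior, bg elsewhere
            ll += m + np.log(z) - np.log(len(scores)) + log_bg[e].sum()
            n = len(scores)
            for j in range(w):
                np.add.at(new_counts[j], e[j:j + n], post)
        # the pseudocounted M-step maximizes a Dirichlet-regularized
        # objective; that penalized value is the monotone quantity
        obj = ll + 0.25 * log_pwm.sum()
        assert obj >= prev_obj - 1e-9, "EM objective decreased"
        if obj - prev_obj < tol and np.isfinite(prev_obj):
            prev_obj = obj
            break
        prev_obj = obj
        pwm = new_counts / new_counts.sum(axis=1, keepdims=True)
    else:
        log.warning("oops_em_discover: EM did not converge in %d iterations", max_iter)
    return pwm, ll


# ---------------------------------------------------------------------------
# PWM library scanning with core-score cutoff
# ---------------------------------------------------------------------------

def read_jaspar_pwms(path, pseudocount: float = 0.25) -> dict[str, PWM]:
    """Read a JASPAR-format text file of count matrices into PWMs."""
    import re
    pwms: dict[str, PWM] = {}
    name, rows = None, {}
    def flush():
        if name and len(rows) == 4:
            mat = np.array([rows[b] for b in BASES], dtype=float).T + pseudocount
            pwms[name] = PWM(mat / mat.sum(axis=1, keepdims=True))
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                flush()
                name, rows = line[1:].split()[0], {}
            elif line:
                m = re.match(r"([ACGT])\s*\[?\s*([0-9. \t]+)\]?", line)
                if m:
                    rows[m.group(1)] = [float(x) for x in m.group(2).split()]
        flush()
    return pwms


def core_positions(pwm: PWM) -> tuple[int, int]:
    """Start/end (half-open) of the 5 consecutive positions of maximal
    summed information content."""
    if pwm.width < 5:
        raise ValidationError("PWM width must be >= 5 for core scoring")
    ic = pwm.information_content()
    sums = np.convolve(ic, np.ones(5), mode="valid")
    start = int(np.argmax(sums))
    return start, start + 5


def core_score(window: str, pwm: PWM) -> float:
    """Match score over the PWM's core, min-max normalized to [0, 1].

    1.0 means every core position shows its most probable base; degenerate
    cores where max == min score 1.0 by convention.
    """
    lo, hi = core_positions(pwm)
    probs = pwm.probs[lo:hi]
    worst, best_ = probs.min(axis=1).sum(), probs.max(axis=1).sum()
    attained = 0.0
    for j, pos in enumerate(range(lo, hi)):
        b = _BASE_IDX.get(window[pos].upper(), -1)
        attained += probs[j, b] if b >= 0 else probs[j].min()
    if best_ == worst:
        return 1.0
    return (attained - worst) / (best_ - worst)


def core_score_scan(sequences: dict[str, str], library: dict[str, PWM],
                    core_cutoff: float = 1.0, both_strands: bool = True
                    ) -> pd.DataFrame:
    """Count core-score hits of each library PWM across the sequences.

    A hit is any offset (either strand when ``both_strands``) whose core
    score reaches ``core_cutoff``.  Returns per-motif total hits and the
    number of hit-bearing sequences.
    """
    if not library:
        raise ValidationError("empty PWM library")
    rows = []
    for mname, pwm in library.items():
        w = pwm.width
        total, bearing = 0, 0
        for sid, seq in sequences.items():
            seq = seq.upper()
            n_hit = 0
            targets = [seq] + ([revcomp(seq)] if both_strands else [])
            for s in targets:
                for off in range(len(s) - w + 1):
                    if core_score(s[off:off + w], pwm) >= core_cutoff:
                        n_hit += 1
            total += n_hit
            bearing += bool(n_hit)
        rows.append({"motif": mname, "n_hits": total, "n_sequences_with_hit": bearing})
    return pd.DataFrame(rows)
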