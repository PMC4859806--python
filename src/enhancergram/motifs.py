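"""PWM handling and binding-site prediction with MAST-like semantics.

Position probability matrices are read from MEME minimal motif files
(via Biopython), optionally averaged into hybrid matrices, converted to
log-odds (base 2, bits), and applied to DNA with a score threshold derived
from an exact p-value computation over the background model.

Coordinates are 0-based half-open on the forward strand.  Two sites overlap
iff their [start, end) intervals share at least one base pair; overlapping
sites cannot be simultaneously bound in the thermodynamic engine.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from Bio import motifs as bio_motifs

__all__ = [
    "PWM",
    "ScoreMatrix",
    "BindingSite",
    "SiteMap",
    "read_motif_matrix",
    "read_motif_matrices",
    "write_meme",
    "average_position_matrices",
    "pvalue_threshold",
    "scan_sequence",
    "scan_canntg",
    "mutate_sites",
    "build_sitemap",
    "default_motifs",
    "MutationTargetError",
]

ALPHABET = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

DEFAULT_PSEUDOCOUNT = 0.01
DEFAULT_BACKGROUND = np.full(4, 0.25)


class MutationTargetError(ValueError):
    """The wild-type subsequence of a mutation is absent or ambiguous."""


@dataclass(frozen=True)
class PWM:
    """Position probability matrix over ACGT; rows sum to 1."""

    name: str
    probs: np.ndarray  # L x 4
    pseudocount: float = DEFAULT_PSEUDOCOUNT

    def __post_init__(self):
        probs = np.asarray(self.probs, dtype=float)
        if probs.ndim != 2 or probs.shape[1] != 4 or probs.shape[0] < 1:
            raise ValueError(f"PWM {self.name!r}: expected an Lx4 matrix")
        if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError(f"PWM {self.name!r}: rows must sum to 1")
        if np.any(probs <= 0):
            raise ValueError(f"PWM {self.name!r}: entries must be > 0 after pseudocount")
        object.__setattr__(self, "probs", probs)

    def __len__(self) -> int:
        return self.probs.shape[0]

    @classmethod
    def from_counts(cls, name: str, rows: np.ndarray,
                    pseudocount: float = DEFAULT_PSEUDOCOUNT) -> "PWM":
        """Build from per-position probabilities or counts, applying the
        pseudocount and renormalizing each row."""
        rows = np.asarray(rows, dtype=float)
        sums = rows.sum(axis=1, keepdims=True)
        if np.any(sums <= 0):
            raise ValueError(f"PWM {name!r}: empty position row")
        probs = rows / sums + pseudocount
        probs /= probs.sum(axis=1, keepdims=True)
        return cls(name, probs, pseudocount)

    @classmethod
    def from_sites(cls, name: str, sites: list[str],
                   pseudocount: float = DEFAULT_PSEUDOCOUNT) -> "PWM":
        """Build from equal-length aligned site sequences."""
        L = len(sites[0])
        if any(len(s) != L for s in sites):
            raise ValueError("aligned sites must have equal length")
        counts = np.zeros((L, 4))
        for s in sites:
            for i, b in enumerate(s.upper()):
                counts[i, _BASE_INDEX[b]] += 1
        return cls.from_counts(name, counts, pseudocount)

    def to_score_matrix(self, background: np.ndarray | None = None) -> "ScoreMatrix":
        bg = DEFAULT_BACKGROUND if background is None else np.asarray(background, float)
        if not np.isclose(bg.sum(), 1.0):
            raise ValueError("background frequencies must sum to 1")
        return ScoreMatrix(self.name, np.log2(self.probs / bg), bg)


@dataclass(frozen=True)
class ScoreMatrix:
    """Log-odds form of a PWM (base 2; scores in bits)."""

    source: str
    logodds: np.ndarray  # L x 4
    background: np.ndarray

    def __len__(self) -> int:
        return self.logodds.shape[0]

    @property
    def max_score(self) -> float:
        return float(self.logodds.max(axis=1).sum())

    @property
    def min_score(self) -> float:
        return float(self.logodds.min(axis=1).sum())

    def reverse_complement(self) -> "ScoreMatrix":
        return ScoreMatrix(self.source, self.logodds[::-1, ::-1].copy(), self.background)


@dataclass(frozen=True)
class BindingSite:
    """A scored TF binding site on the forward strand of one sequence."""

    tf: str
    start: int
    end: int
    strand: str
    score: float
    affinity: float  # score / max achievable matrix score, in (0, 1]
    name: str = ""

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError("site must have end > start")

    @property
    def center(self) -> float:
        return (self.start + self.end) / 2.0


@dataclass
class SiteMap:
    """Ordered, annotated binding sites on one enhancer sequence."""

    sequence_id: str
    length: int
    sites: list[BindingSite] = field(default_factory=list)

    def __post_init__(self):
        self.sites = sorted(self.sites, key=lambda s: (s.start, s.end))

    def __len__(self) -> int:
        return len(self.sites)

    @property
    def overlap_pairs(self) -> set[tuple[int, int]]:
        pairs = set()
        for i, a in enumerate(self.sites):
            for j in range(i + 1, len(self.sites)):
                b = self.sites[j]
                if b.start >= a.end:
                    break
                pairs.add((i, j))
                pairs.add((j, i))
        return pairs

    def without(self, names: set[str] | list[str]) -> "SiteMap":
        """Site map with the named sites deleted (knockout by deletion)."""
        names = set(names)
        missing = names - {s.name for s in self.sites}
        if missing:
            raise KeyError(f"unknown site names: {sorted(missing)}")
        keep = [s for s in self.sites if s.name not in names]
        return SiteMap(self.sequence_id, self.length, keep)

    def shifted(self, offset: int, new_id: str | None = None) -> "SiteMap":
        sites = [replace(s, start=s.start + offset, end=s.end + offset) for s in self.sites]
        return SiteMap(new_id or self.sequence_id, self.length, sites)

    def to_json(self) -> dict:
        return {
            "sequence_id": self.sequence_id,
            "length": self.length,
            "sites": [
                {
                    "tf": s.tf, "start": s.start, "end": s.end, "strand": s.strand,
                    "score": s.score, "affinity": s.affinity, "name": s.name,
                }
                for s in self.sites
            ],
        }

    @classmethod
    def from_json(cls, payload: dict) -> "SiteMap":
        sites = [BindingSite(**d) for d in payload["sites"]]
        return cls(payload["sequence_id"], payload["length"], sites)


# ----------------------------------------------------------------------
# MEME minimal format I/O
# ----------------------------------------------------------------------

def read_motif_matrices(path, pseudocount: float = DEFAULT_PSEUDOCOUNT) -> list[PWM]:
    """Read all motifs from a MEME minimal motif file."""
    with open(path) as fh:
        text = fh.read()
    if "ALPHABET" in text:
        alpha_line = next(l for l in text.splitlines() if l.startswith("ALPHABET"))
        letters = alpha_line.split("=", 1)[-1].strip().split()[0]
        if set(letters.upper()) - set("ACGT"):
            raise ValueError(
                f"{path}: unsupported alphabet {letters!r}; only DNA (ACGT) is supported"
            )
    try:
        records = bio_motifs.parse(io.StringIO(text), "minimal")
    except Exception as exc:  # report the offending line where possible
        lineno = _guess_bad_line(text)
        raise ValueError(f"{path}: malformed MEME minimal file near line {lineno}: {exc}") from exc
    out = []
    for rec in records:
        counts = np.column_stack([rec.counts[b] for b in ALPHABET])
        out.append(PWM.from_counts(rec.name, counts, pseudocount))
    if not out:
        raise ValueError(f"{path}: no motifs found")
    return out


def read_motif_matrix(path, pseudocount: float = DEFAULT_PSEUDOCOUNT) -> PWM:
    """Read the first motif from a MEME minimal motif file."""
    return read_motif_matrices(path, pseudocount)[0]


def _guess_bad_line(text: str) -> int:
    for i, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith(("MEME", "ALPHABET", "strands",
                                               "Background", "MOTIF", "letter-probability")):
            continue
        fields = stripped.split()
        if any(not _is_float(f) for f in fields) or len(fields) != 4:
            return i
    return 1


def _is_float(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False


def write_meme(pwms: list[PWM], path, background: np.ndarray | None = None) -> None:
    """Write motifs in MEME minimal format."""
    bg = DEFAULT_BACKGROUND if background is None else np.asarray(background, float)
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write("Background letter frequencies\n")
        fh.write(" ".join(f"{b} {f:.5f}" for b, f in zip(ALPHABET, bg)) + "\n\n")
        for pwm in pwms:
            fh.write(f"MOTIF {pwm.name}\n")
            # large nsites: MEME parsers reconstruct counts as prob * nsites,
            # so a small value would quantize the probabilities on read-back
            fh.write(
                f"letter-probability matrix: alength= 4 w= {len(pwm)} "
                f"nsites= 1000000 E= 0\n"
            )
            for row in pwm.probs:
                fh.write(" ".join(f"{v:.6f}" for v in row) + "\n")
            fh.write("\n")


def average_position_matrices(a: PWM, b: PWM, name: str | None = None) -> PWM:
    """Arithmetic mean of two position probability matrices (hybrid PWM).

    The hybrid's log-odds are computed from the averaged probabilities, not
    by averaging log-odds.
    """
    if len(a) != len(b):
        raise ValueError(f"cannot average matrices of lengths {len(a)} and {len(b)}")
    return PWM(name or f"{a.name}+{b.name}", (a.probs + b.probs) / 2.0, a.pseudocount)


# ----------------------------------------------------------------------
# p-value thresholds by exact dynamic programming
# ----------------------------------------------------------------------

def pvalue_threshold(m: ScoreMatrix, p: float, granularity: float = 1e-3) -> float:
    """Score threshold (bits) whose background tail probability is the
    largest value not exceeding ``p``.

    Computed exactly on a score grid of width ``granularity`` bits: the full
    distribution of word scores under the background model is built by
    dynamic programming over positions; the threshold sits just below the
    lowest achievable score level whose upper-tail probability is <= p
    (a slack of ``L * granularity`` absorbs per-position rounding).  The
    admitted word set is exact provided distinct achievable scores differ by
    more than ``2 * L * granularity``.
    """
    if not (0.0 < p < 1.0):
        raise ValueError(f"p must lie in (0, 1), got {p}")
    scores = np.round(m.logodds / granularity).astype(np.int64)
    L = scores.shape[0]
    dist = np.ones(1)
    cur_lo = 0
    cur_hi = 0
    for i in range(L):
        row = scores[i]
        new_lo = cur_lo + int(row.min())
        new_hi = cur_hi + int(row.max())
        new = np.zeros(new_hi - new_lo + 1)
        for b in range(4):
            shift = int(row[b]) - int(row.min())
            new[shift: shift + len(dist)] += dist * m.background[b]
        dist = new
        cur_lo, cur_hi = new_lo, new_hi
    tail = np.cumsum(dist[::-1])[::-1]  # tail[k] = P(score >= cur_lo + k)
    achievable = dist > 0
    ok = np.nonzero((tail <= p + 1e-12) & achievable)[0]
    if len(ok) == 0:
        # even the maximum score is more probable than p: no word admitted
        return (cur_hi + 1) * granularity
    return (cur_lo + int(ok[0]) - L) * granularity


# ----------------------------------------------------------------------
# scanning
# ----------------------------------------------------------------------

def _encode(seq: str) -> np.ndarray:
    table = np.full(256, 4, dtype=np.int8)
    for b, i in _BASE_INDEX.items():
        table[ord(b)] = i
        table[ord(b.lower())] = i
    return table[np.frombuffer(seq.encode(), dtype=np.uint8)]


def _window_scores(codes: np.ndarray, m: ScoreMatrix) -> np.ndarray:
    """Score of every length-L window; N positions contribute 0 bits."""
    L = len(m)
    n = len(codes) - L + 1
    if n <= 0:
        return np.empty(0)
    lod = np.column_stack([m.logodds, np.zeros(len(m))])  # 5th column: N -> 0
    out = np.zeros(n)
    for i in range(L):
        out += lod[i, codes[i: i + n]]
    return out


def scan_sequence(seq: str, m: ScoreMatrix, threshold: float,
                  tf: str | None = None) -> list[BindingSite]:
    """All sites on both strands scoring >= threshold.

    Coordinates are reported on the forward strand.  When the forward and
    reverse-strand windows at the same position both pass, only the higher
    scoring strand is reported (MAST-like collapse).
    """
    codes = _encode(seq)
    L = len(m)
    if len(codes) < L:
        return []
    fwd = _window_scores(codes, m)
    rev = _window_scores(codes, m.reverse_complement())
    tfname = tf or m.source
    max_score = m.max_score
    sites = []
    for s in np.nonzero((fwd >= threshold) | (rev >= threshold))[0]:
        if fwd[s] >= rev[s]:
            strand, score = "+", fwd[s]
        else:
            strand, score = "-", rev[s]
        sites.append(BindingSite(tfname, int(s), int(s) + L, strand,
                                 float(score), min(1.0, float(score) / max_score)))
    return sites


def scan_canntg(seq: str, tf: str = "bHLH", affinity: float = 0.8) -> list[BindingSite]:
    """Literal CANNTG E-box matcher (palindromic; reported on + strand)."""
    seq = seq.upper()
    sites = []
    for s in range(len(seq) - 5):
        word = seq[s: s + 6]
        if word.startswith("CA") and word.endswith("TG") and "N" not in word:
            sites.append(BindingSite(tf, s, s + 6, "+", 0.0, affinity))
    return sites


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


# ----------------------------------------------------------------------
# site mutagenesis
# ----------------------------------------------------------------------

def mutate_sites(seq: str, mutations: list[tuple[str, str]],
                 rescan: tuple[ScoreMatrix, float] | None = None) -> str:
    """Apply wild-type -> replacement substitutions to a sequence.

    Each wild-type subsequence must occur exactly once.  If ``rescan`` is
    given as (matrix, threshold), the mutated region is rescanned and a
    warning is issued if a site of that matrix still passes the threshold
    (mutations are expected to reduce binding scores to near background).
    """
    out = seq.upper()
    for wt, repl in mutations:
        wt = wt.upper()
        n = out.count(wt)
        if n == 0:
            raise MutationTargetError(f"wild-type subsequence {wt!r} not found")
        if n > 1:
            raise MutationTargetError(f"wild-type subsequence {wt!r} occurs {n} times")
        pos = out.index(wt)
        out = out[:pos] + repl.upper() + out[pos + len(wt):]
        if rescan is not None:
            matrix, threshold = rescan
            pad = len(matrix)
            lo = max(0, pos - pad)
            hi = min(len(out), pos + len(repl) + pad)
            if scan_sequence(out[lo:hi], matrix, threshold):
                warnings.warn(
                    f"mutated region still contains a {matrix.source} site above "
                    f"threshold after {wt}->{repl}", stacklevel=2,
                )
    return out


# ----------------------------------------------------------------------
# site-map assembly
# ----------------------------------------------------------------------

def build_sitemap(sequence_id: str, seq: str,
                  matrices: dict[str, tuple[ScoreMatrix, float]],
                  bhlh: str | None = "literal") -> SiteMap:
    """Scan a sequence with per-TF matrices and assemble a SiteMap.

    ``matrices`` maps TF name -> (ScoreMatrix, threshold).  ``bhlh`` selects
    E-box handling: "literal" matches CANNTG hexamers, None disables bHLH
    annotation, and any TF key present in ``matrices`` takes precedence.
    """
    sites: list[BindingSite] = []
    for tfname, (matrix, threshold) in matrices.items():
        sites.extend(scan_sequence(seq, matrix, threshold, tf=tfname))
    if bhlh == "literal" and "bHLH" not in matrices:
        sites.extend(scan_canntg(seq))
    counters: dict[str, int] = {}
    named = []
    for s in sorted(sites, key=lambda s: (s.start, s.end)):
        counters[s.tf] = counters.get(s.tf, 0) + 1
        named.append(replace(s, name=f"{s.tf}{counters[s.tf]}"))
    return SiteMap(sequence_id, len(seq), named)


# ----------------------------------------------------------------------
# packaged stand-in motifs
# ----------------------------------------------------------------------

# Footprinted wild-type site sequences on the rho neurectodermal enhancer.
# These are the experimentally characterized site sequences targeted by the
# knockout mutations; the packaged PWMs built from them are synthetic
# stand-ins for the published Dorsal/Twist/Snail matrices, which are not
# redistributed here.
FOOTPRINTED_SITES = {
    "Dorsal": ["GGGAAAAACAC", "CGGAATTTCCT", "GGGAAATTCCC", "GGGAAAGGCCA"],
    "Twist": ["CGCATATGTT", "AGCACATGTT"],
    "Snail": ["CAACTTGCGG", "CACCTTGCTG", "CCACTTGCGC"],
    "bHLH": ["CATTTG", "CAAGTG"],
}


def default_motifs(pseudocount: float = DEFAULT_PSEUDOCOUNT,
                   include_bhlh: bool = False) -> dict[str, PWM]:
    """Stand-in PWMs built from the footprinted site sequences."""
    tfs = ["Dorsal", "Twist", "Snail"] + (["bHLH"] if include_bhlh else [])
    return {tf: PWM.from_sites(tf, FOOTPRINTED_SITES[tf], pseudocount) for tf in tfs}
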