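"""The 1920-dimensional protein sequence descriptor engine.

Six descriptor families in the pseudo amino acid composition tradition are
computed and concatenated in a fixed order:

====================  ====  =========================================================
group                 dim   content
====================  ====  =========================================================
``aac_dc``             420  amino-acid composition (20) + dipeptide composition (400)
``autocorr``           720  Moreau-Broto / Moran / Geary autocorrelation,
                            8 standardized property scales x 30 lags
``ctd``                147  composition-transition-distribution over 7 properties
``order``              160  sequence-order-coupling numbers + quasi-sequence-order,
                            two physicochemical distance matrices
``pseaac``             130  type I (20+lambda) and type II amphiphilic (20+2*lambda)
                            pseudo amino acid composition
``ctriad``             343  conjoint-triad counts over a 7-class alphabet, min-max
                            normalized
====================  ====  =========================================================

At the default configuration the total is exactly 1920 features.  Feature
names follow the protr naming convention (``prop5.G2.residue25``,
``Schneider.Xr.S``, ``VS333``, ...) so selected features can be addressed by
name across tools.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from hashlib import sha256
from math import ceil

import numpy as np

from . import _tables as T
from .sequence_io import ProteinSequence

__all__ = [
    "DescriptorConfig",
    "FeatureVector",
    "extract_aac_dc",
    "extract_autocorrelation",
    "extract_ctd",
    "extract_order",
    "extract_pseaac",
    "extract_ctriad",
    "extract_all",
    "feature_names",
    "group_spans",
]

_AA = T.AMINO_ACIDS


@dataclass(frozen=True)
class DescriptorConfig:
    """Tunable parameters of the descriptor families.

    Defaults are the unique standard configuration that yields the group
    dimensionalities 420/720/147/160/130/343 (total 1920).
    """

    nlag_autocorr: int = 30
    nlag_order: int = 30
    weight_qso: float = 0.1
    lambda_pseaac: int = 30
    weight_pseaac: float = 0.05
    autocorr_properties: tuple[str, ...] = tuple(T.AUTOCORR_SCALES)

    def fingerprint(self) -> str:
        """Stable hash identifying this configuration (stored with models)."""
        payload = (
            f"{self.nlag_autocorr}|{self.nlag_order}|{self.weight_qso}|"
            f"{self.lambda_pseaac}|{self.weight_pseaac}|"
            f"{','.join(self.autocorr_properties)}|"
            f"{sorted(T.table_checksums().items())}"
        )
        return sha256(payload.encode()).hexdigest()[:16]


@dataclass
class FeatureVector:
    """An ordered, named feature encoding of one sequence."""

    sequence_id: str
    values: np.ndarray
    names: list[str]
    group_spans: dict[str, tuple[int, int]] = field(default_factory=dict)

    def group(self, name: str) -> np.ndarray:
        off, length = self.group_spans[name]
        return self.values[off:off + length]

    def __len__(self) -> int:
        return len(self.values)


def _indices(seq: str) -> np.ndarray:
    try:
        return np.array([T.AA_INDEX[c] for c in seq], dtype=np.intp)
    except KeyError as e:  # pragma: no cover - validation happens upstream
        raise ValueError(f"non-canonical residue {e.args[0]!r}") from None


# ---------------------------------------------------------------------------
# amino-acid + dipeptide composition (420)
# ---------------------------------------------------------------------------

def extract_aac_dc(seq: ProteinSequence) -> np.ndarray:
    """Relative residue frequencies (20) and adjacent-pair frequencies (400)."""
    s = seq.residues
    if len(s) < 2:
        raise ValueError("aac_dc requires length >= 2 (no dipeptides otherwise)")
    idx = _indices(s)
    aac = np.bincount(idx, minlength=20) / len(s)
    pair = idx[:-1] * 20 + idx[1:]
    dc = np.bincount(pair, minlength=400) / (len(s) - 1)
    return np.concatenate([aac, dc])


# ---------------------------------------------------------------------------
# autocorrelation descriptors (720)
# ---------------------------------------------------------------------------

def extract_autocorrelation(seq: ProteinSequence,
                            cfg: DescriptorConfig = DescriptorConfig()) -> np.ndarray:
    """Moreau-Broto, Moran and Geary autocorrelation at lags 1..nlag.

    Each property scale is standardized to mean 0, sd 1 over the 20 residues
    before the sequence series is formed.  Zero-variance series (e.g.
    homopolymers) yield 0 for Moran and Geary by convention.
    """
    s = seq.residues
    L = len(s)
    nlag = cfg.nlag_autocorr
    if L <= nlag:
        raise ValueError(f"autocorr requires length > nlag ({nlag}); got {L}")
    idx = _indices(s)
    out: list[float] = []
    series = [T.standardize(T.AUTOCORR_SCALES[p])[idx] for p in cfg.autocorr_properties]
    for kind in ("mb", "moran", "geary"):
        for p in series:
            pbar = p.mean()
            centered = p - pbar
            # constant series (homopolymers) have zero variance by definition
            ss = 0.0 if p.max() == p.min() else float(centered @ centered)
            for d in range(1, nlag + 1):
                a, b = p[:-d], p[d:]
                if kind == "mb":
                    out.append(float(a @ b) / (L - d))
                elif kind == "moran":
                    if ss == 0.0:
                        out.append(0.0)
                    else:
                        num = float((a - pbar) @ (b - pbar)) / (L - d)
                        out.append(num / (ss / L))
                else:
                    if ss == 0.0:
                        out.append(0.0)
                    else:
                        num = float(((a - b) ** 2).sum()) / (2 * (L - d))
                        out.append(num / (ss / (L - 1)))
    return np.array(out)


# ---------------------------------------------------------------------------
# composition / transition / distribution (147)
# ---------------------------------------------------------------------------

def _ctd_groups_of(seq_idx_free: str, groups: tuple[str, str, str]) -> np.ndarray:
    lut = {}
    for g, members in enumerate(groups):
        for aa in members:
            lut[aa] = g
    return np.array([lut[c] for c in seq_idx_free], dtype=np.intp)


def extract_ctd(seq: ProteinSequence,
                cfg: DescriptorConfig = DescriptorConfig()) -> np.ndarray:
    """Composition, transition and distribution descriptors.

    Per property: 3 group fractions; 3 unordered between-group adjacent-pair
    frequencies (over L-1 pairs); and for each group the sequence positions
    (percent of L) of its first, 25th-, 50th-, 75th-percentile and last
    member.  The k-th occurrence for percentile q is ``ceil(q * count)``
    (with the first occurrence for q=0); empty groups contribute zeros.
    """
    s = seq.residues
    L = len(s)
    if L < 2:
        raise ValueError("ctd requires length >= 2")
    comp: list[float] = []
    tran: list[float] = []
    dist: list[float] = []
    for _, groups in T.CTD_PROPERTIES:
        g = _ctd_groups_of(s, groups)
        counts = np.bincount(g, minlength=3)
        comp.extend(counts / L)
        a, b = g[:-1], g[1:]
        for x, y in ((0, 1), (0, 2), (1, 2)):
            tran.append(float(np.sum(((a == x) & (b == y)) | ((a == y) & (b == x))) / (L - 1)))
        for grp in range(3):
            pos = np.flatnonzero(g == grp) + 1  # 1-based positions
            n = len(pos)
            if n == 0:
                dist.extend([0.0] * 5)
                continue
            for q in (0.0, 0.25, 0.50, 0.75, 1.0):
                k = max(1, ceil(q * n))
                dist.append(100.0 * pos[k - 1] / L)
    return np.array(comp + tran + dist)


# ---------------------------------------------------------------------------
# sequence-order-coupling numbers + quasi-sequence-order (160)
# ---------------------------------------------------------------------------

_DIST_MATS = (("Schneider", T.SCHNEIDER_WREDE), ("Grantham", T.GRANTHAM))


def extract_order(seq: ProteinSequence,
                  cfg: DescriptorConfig = DescriptorConfig()) -> np.ndarray:
    """Sequence-order-coupling numbers tau_d and quasi-sequence-order.

    For each distance matrix: ``tau_d = sum_i dist(R_i, R_{i+d})^2`` for
    d = 1..nlag; then QSO components ``f_r / (sum f + w * sum tau)`` (20)
    followed by ``w * tau_d / (sum f + w * sum tau)`` (nlag), with f the
    relative residue frequencies.
    """
    s = seq.residues
    L = len(s)
    nlag = cfg.nlag_order
    if L <= nlag:
        raise ValueError(f"order requires length > nlag ({nlag}); got {L}")
    idx = _indices(s)
    f = np.bincount(idx, minlength=20) / L
    socn: list[float] = []
    qso: list[float] = []
    for _, mat in _DIST_MATS:
        taus = np.array([
            float((mat[idx[:-d], idx[d:]] ** 2).sum()) for d in range(1, nlag + 1)
        ])
        socn.extend(taus)
        denom = f.sum() + cfg.weight_qso * taus.sum()
        qso.extend(f / denom)
        qso.extend(cfg.weight_qso * taus / denom)
    return np.array(socn + qso)


# ---------------------------------------------------------------------------
# pseudo amino acid composition, type I and amphiphilic type II (130)
# ---------------------------------------------------------------------------

def extract_pseaac(seq: ProteinSequence,
                   cfg: DescriptorConfig = DescriptorConfig()) -> np.ndarray:
    """Chou's type I PseAAC (20+lambda) and type II amphiphilic (20+2*lambda).

    Type I correlation: ``theta_j`` is the sequence mean of the squared
    differences of three standardized scales (hydrophobicity,
    hydrophilicity, side-chain mass) at lag j.  Type II interleaves raw
    hydrophobicity- and hydrophilicity-product correlations per lag.
    """
    s = seq.residues
    L = len(s)
    lam = cfg.lambda_pseaac
    w = cfg.weight_pseaac
    if L <= lam:
        raise ValueError(f"pseaac requires length > lambda ({lam}); got {L}")
    idx = _indices(s)
    h1 = T.standardize(T.PSEAAC_HYDROPHOBICITY)[idx]
    h2 = T.standardize(T.PSEAAC_HYDROPHILICITY)[idx]
    m = T.standardize(T.PSEAAC_MASS)[idx]
    f = np.bincount(idx, minlength=20) / L

    thetas = np.array([
        float(((h1[:-j] - h1[j:]) ** 2 + (h2[:-j] - h2[j:]) ** 2
               + (m[:-j] - m[j:]) ** 2).mean()) / 3.0
        for j in range(1, lam + 1)
    ])
    denom1 = f.sum() + w * thetas.sum()
    type1 = np.concatenate([f / denom1, w * thetas / denom1])

    taus = np.empty(2 * lam)
    for j in range(1, lam + 1):
        taus[2 * j - 2] = float((h1[:-j] * h1[j:]).mean())
        taus[2 * j - 1] = float((h2[:-j] * h2[j:]).mean())
    denom2 = f.sum() + w * taus.sum()
    type2 = np.concatenate([f / denom2, w * taus / denom2])
    return np.concatenate([type1, type2])


# ---------------------------------------------------------------------------
# conjoint triad (343)
# ---------------------------------------------------------------------------

_CT_LUT = {aa: k for k, cls in enumerate(T.CTRIAD_CLASSES) for aa in cls}


def extract_ctriad(seq: ProteinSequence,
                   cfg: DescriptorConfig = DescriptorConfig()) -> np.ndarray:
    """Conjoint-triad descriptors: 7-class triad counts, min-max normalized.

    Counts of the L-2 overlapping class triads fill 343 bins; each bin is
    normalized as ``(f - min f) / max f``.
    """
    s = seq.residues
    if len(s) < 3:
        raise ValueError("ctriad requires length >= 3")
    g = np.array([_CT_LUT[c] for c in s], dtype=np.intp)
    code = g[:-2] * 49 + g[1:-1] * 7 + g[2:]
    f = np.bincount(code, minlength=343).astype(float)
    fmax = f.max()
    if fmax == 0:  # pragma: no cover - impossible for L >= 3
        return f
    return (f - f.min()) / fmax


# ---------------------------------------------------------------------------
# concatenation + naming
# ---------------------------------------------------------------------------

_GROUP_FUNCS = (
    ("aac_dc", lambda s, c: extract_aac_dc(s)),
    ("autocorr", extract_autocorrelation),
    ("ctd", extract_ctd),
    ("order", extract_order),
    ("pseaac", extract_pseaac),
    ("ctriad", extract_ctriad),
)


def group_spans(cfg: DescriptorConfig = DescriptorConfig()) -> dict[str, tuple[int, int]]:
    """Offset and length of every descriptor group in the concatenated vector."""
    lengths = {
        "aac_dc": 420,
        "autocorr": 3 * len(cfg.autocorr_properties) * cfg.nlag_autocorr,
        "ctd": 147,
        "order": 2 * cfg.nlag_order + 2 * (20 + cfg.nlag_order),
        "pseaac": (20 + cfg.lambda_pseaac) + (20 + 2 * cfg.lambda_pseaac),
        "ctriad": 343,
    }
    spans = {}
    off = 0
    for name, _ in _GROUP_FUNCS:
        spans[name] = (off, lengths[name])
        off += lengths[name]
    return spans


def feature_names(cfg: DescriptorConfig = DescriptorConfig()) -> list[str]:
    """Ordered names for every feature at this configuration."""
    names: list[str] = list(_AA)
    names += [a + b for a in _AA for b in _AA]
    for kind in ("MoreauBroto", "Moran", "Geary"):
        for prop in cfg.autocorr_properties:
            names += [f"{kind}.{prop}.lag{d}" for d in range(1, cfg.nlag_autocorr + 1)]
    comp = [f"{pname}.Group{k}" for pname, _ in T.CTD_PROPERTIES for k in (1, 2, 3)]
    tran = [f"prop{i}.Tr{t}" for i in range(1, 8) for t in ("1221", "1331", "2332")]
    dist = [
        f"prop{i}.G{k}.residue{p}"
        for i in range(1, 8)
        for k in (1, 2, 3)
        for p in (0, 25, 50, 75, 100)
    ]
    names += comp + tran + dist
    for mname, _ in _DIST_MATS:
        names += [f"{mname}.{d}" for d in range(1, cfg.nlag_order + 1)]
    for mname, _ in _DIST_MATS:
        names += [f"{mname}.Xr.{a}" for a in _AA]
        names += [f"{mname}.Xd.{d}" for d in range(1, cfg.nlag_order + 1)]
    names += [f"Xc1.{a}" for a in _AA]
    names += [f"Xc2.lambda.{j}" for j in range(1, cfg.lambda_pseaac + 1)]
    names += [f"Pc1.{a}" for a in _AA]
    for j in range(1, cfg.lambda_pseaac + 1):
        names += [f"Pc2.Hydrophobicity.{j}", f"Pc2.Hydrophilicity.{j}"]
    names += [f"VS{i}{j}{k}" for i in range(1, 8) for j in range(1, 8) for k in range(1, 8)]
    return names


def extract_all(seq: ProteinSequence,
                cfg: DescriptorConfig = DescriptorConfig()) -> FeatureVector:
    """Concatenate the six descriptor groups into one named feature vector.

    Group order is fixed (aac_dc, autocorr, ctd, order, pseaac, ctriad); at
    the default configuration the result has exactly 1920 components.
    Errors from a group are re-raised with the group name attached.
    """
    parts = []
    for gname, fn in _GROUP_FUNCS:
        try:
            parts.append(fn(seq, cfg))
        except ValueError as e:
            raise ValueError(f"[{gname}] {seq.id}: {e}") from e
    values = np.concatenate(parts)
    if not np.all(np.isfinite(values)):
        raise ValueError(f"non-finite descriptor values for {seq.id}")
    return FeatureVector(
        sequence_id=seq.id,
        values=values,
        names=feature_names(cfg),
        group_spans=group_spans(cfg),
    )


def extract_matrix(seqs, cfg: DescriptorConfig = DescriptorConfig()) -> "np.ndarray":
    """Stack :func:`extract_all` over sequences into an (n, d) array."""
    return np.stack([extract_all(s, cfg).values for s in seqs])
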