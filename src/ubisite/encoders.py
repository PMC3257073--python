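"""Window-to-feature-vector encoders and the feature registry.

Four feature families describe a lysine-centered peptide window:

* **AAC** — 20 single-residue compositions plus 66 merged dipeptide
  frequencies on an 11-group reduced amino-acid alphabet (86 values);
* **PSSM** — the w stacked rows of the min-max-normalized position-specific
  scoring matrix covering the window (20*w values, 420 at w=21);
* **FACTOR** — the five Atchley physicochemical factors (charge, codon
  diversity, volume, secondary structure, polarity) of each of the 20
  flanking sites; the invariant central lysine is excluded (100 values);
* **DISORDER** — one intrinsic-disorder score per window site (w values).

At the default w=21 the concatenation is 86 + 420 + 100 + 21 = 627 features.
Padding residues ('X') are inert in every family: they are excluded from
composition denominators, contribute zero rows/vectors, and score 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .data_io import AMINO_ACIDS, PAD, PeptideWindow, TrackProvider

AAC, PSSM, FACTOR, DISORDER = "AAC", "PSSM", "FACTOR", "DISORDER"
ALL_FAMILIES = (AAC, PSSM, FACTOR, DISORDER)

#: Default 11-group physicochemical clustering of the 20 amino acids.
DEFAULT_GROUPS: tuple[frozenset[str], ...] = tuple(
    frozenset(g)
    for g in ("A", "G", "P", "C", "ST", "NQ", "DE", "KR", "H", "ILMV", "FWY")
)


@dataclass(frozen=True)
class GroupScheme:
    """An ordered partition of the 20 amino acids into 11 groups."""

    groups: tuple[frozenset[str], ...] = DEFAULT_GROUPS
    name: str = "default-11"

    def __post_init__(self) -> None:
        if len(self.groups) != 11:
            raise ValueError("scheme must have exactly 11 groups")
        union = set().union(*self.groups)
        if union != set(AMINO_ACIDS):
            raise ValueError("groups must cover the 20 amino acids exactly")
        if sum(len(g) for g in self.groups) != 20:
            raise ValueError("groups must be pairwise disjoint")

    def group_of(self, aa: str) -> int:
        for i, g in enumerate(self.groups):
            if aa in g:
                return i
        raise KeyError(aa)


def load_factor_table() -> dict[str, np.ndarray]:
    """Load the bundled five-factor physicochemical table (Atchley solution).

    'X' maps to the zero vector.
    """
    with resources.files("ubisite.data").joinpath("atchley_factors.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", index_col="aa")
    table = {aa: df.loc[aa].to_numpy(dtype=float) for aa in df.index}
    if set(table) != set(AMINO_ACIDS):
        raise ValueError("factor table must cover exactly the 20 amino acids")
    table[PAD] = np.zeros(5)
    return table


@dataclass(frozen=True)
class FeatureDescriptor:
    id: str
    family: str
    window_site: int | None  # 1..w, or None for site-free (AAC) features
    detail: str = ""


@dataclass
class EncoderConfig:
    """Everything that fixes the feature space."""

    w: int = 21
    families: tuple[str, ...] = ALL_FAMILIES
    scheme: GroupScheme = field(default_factory=GroupScheme)

    def __post_init__(self) -> None:
        if self.w % 2 == 0 or self.w < 1:
            raise ValueError("w must be odd and positive")
        unknown = set(self.families) - set(ALL_FAMILIES)
        if unknown:
            raise ValueError(f"unknown feature families {sorted(unknown)}")


class FeatureRegistry:
    """Ordered, named feature space for a fixed :class:`EncoderConfig`."""

    def __init__(self, config: EncoderConfig | None = None) -> None:
        self.config = config or EncoderConfig()
        self.descriptors: list[FeatureDescriptor] = []
        w = self.config.w
        center = (w + 1) // 2
        scheme = self.config.scheme
        if AAC in self.config.families:
            for aa in AMINO_ACIDS:
                self.descriptors.append(
                    FeatureDescriptor(f"AAC:comp:{aa}", AAC, None, f"composition of {aa}")
                )
            for i in range(11):
                for j in range(i, 11):
                    gi = "".join(sorted(scheme.groups[i]))
                    gj = "".join(sorted(scheme.groups[j]))
                    self.descriptors.append(
                        FeatureDescriptor(
                            f"AAC:dipep:g{i:02d}-g{j:02d}",
                            AAC,
                            None,
                            f"dipeptide [{gi}]x[{gj}]",
                        )
                    )
        if PSSM in self.config.families:
            for site in range(1, w + 1):
                for aa in AMINO_ACIDS:
                    self.descriptors.append(
                        FeatureDescriptor(
                            f"PSSM:s{site:02d}:{aa}", PSSM, site,
                            f"normalized log-odds of {aa} at window site {site}",
                        )
                    )
        if FACTOR in self.config.families:
            for site in range(1, w + 1):
                if site == center:
                    continue
                for k in range(1, 6):
                    self.descriptors.append(
                        FeatureDescriptor(
                            f"FACTOR:s{site:02d}:f{k}", FACTOR, site,
                            f"factor {k} at window site {site}",
                        )
                    )
        if DISORDER in self.config.families:
            for site in range(1, w + 1):
                self.descriptors.append(
                    FeatureDescriptor(
                        f"DIS:s{site:02d}", DISORDER, site,
                        f"disorder score at window site {site}",
                    )
                )
        self.ids: list[str] = [d.id for d in self.descriptors]
        if len(set(self.ids)) != len(self.ids):
            raise AssertionError("duplicate feature ids in registry")
        self._index = {fid: i for i, fid in enumerate(self.ids)}

    def __len__(self) -> int:
        return len(self.descriptors)

    def index_of(self, feature_id: str) -> int:
        return self._index[feature_id]

    def descriptor(self, feature_id: str) -> FeatureDescriptor:
        return self.descriptors[self._index[feature_id]]

    def family_counts(self) -> dict[str, int]:
        counts = {fam: 0 for fam in ALL_FAMILIES}
        for d in self.descriptors:
            counts[d.family] += 1
        return counts

    def fingerprint(self) -> str:
        import hashlib

        return hashlib.sha256("\n".join(self.ids).encode()).hexdigest()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.ids,
                "family": [d.family for d in self.descriptors],
                "window_site": [d.window_site for d in self.descriptors],
                "detail": [d.detail for d in self.descriptors],
            }
        )


# ---------------------------------------------------------------------------
# family encoders
# ---------------------------------------------------------------------------

def encode_aac(
    window: PeptideWindow,
    scheme: GroupScheme | None = None,
    merged: bool = True,
) -> tuple[np.ndarray, list[str]]:
    """Composition features: 20 single-residue + dipeptide frequencies.

    With ``merged=True`` (default) the 121 ordered group-pair dipeptides are
    merged into 66 unordered categories, giving 86 values; ``merged=False``
    returns the intermediate 20 + 121 = 141-length representation.

    'X' residues are excluded from the composition denominator and any
    adjacent pair touching an 'X' is skipped; dipeptide counts are
    normalized by the number of counted pairs.
    """
    scheme = scheme or GroupScheme()
    residues = window.residues
    if not residues:
        raise ValueError("empty window")
    n_real = sum(1 for aa in residues if aa != PAD)
    comp = np.zeros(20)
    if n_real:
        for aa in residues:
            if aa != PAD:
                comp[AMINO_ACIDS.index(aa)] += 1
        comp /= n_real
    comp_names = [f"AAC:comp:{aa}" for aa in AMINO_ACIDS]

    ordered = np.zeros((11, 11))
    n_pairs = 0
    for a, b in zip(residues, residues[1:]):
        if a == PAD or b == PAD:
            continue
        ordered[scheme.group_of(a), scheme.group_of(b)] += 1
        n_pairs += 1
    if merged:
        vals, names = [], []
        for i in range(11):
            for j in range(i, 11):
                c = ordered[i, j] if i == j else ordered[i, j] + ordered[j, i]
                vals.append(c / n_pairs if n_pairs else 0.0)
                names.append(f"AAC:dipep:g{i:02d}-g{j:02d}")
        dipep = np.array(vals)
    else:
        dipep = (ordered / n_pairs if n_pairs else ordered).ravel()
        names = [f"AAC:odipep:g{i:02d}-g{j:02d}" for i in range(11) for j in range(11)]
    return np.concatenate([comp, dipep]), comp_names + names


def encode_pssm(
    window: PeptideWindow, pssm, w: int | None = None
) -> tuple[np.ndarray, list[str]]:
    """Stack the w normalized PSSM rows covering the window (20 each).

    Rows falling outside the protein contribute 20 zeros.
    """
    w = w or window.w
    half = (w - 1) // 2
    L = pssm.normalized.shape[0]
    blocks = []
    for offset in range(-half, half + 1):
        pos = window.center + offset  # 1-based
        if 1 <= pos <= L:
            blocks.append(pssm.normalized[pos - 1])
        else:
            blocks.append(np.zeros(20))
    names = [
        f"PSSM:s{site:02d}:{aa}" for site in range(1, w + 1) for aa in AMINO_ACIDS
    ]
    return np.concatenate(blocks), names


def encode_factors(
    window: PeptideWindow, table: dict[str, np.ndarray] | None = None
) -> tuple[np.ndarray, list[str]]:
    """Five factor values per flanking site; the central lysine is skipped.

    The window has w sites but the center is always 'K', so its factors are
    invariant and carry no signal: 5 * (w - 1) values (100 at w=21).
    """
    table = table if table is not None else load_factor_table()
    center = window.center_site
    vals, names = [], []
    for site, aa in enumerate(window.residues, start=1):
        if site == center:
            continue
        vals.append(table[aa])
        names.extend(f"FACTOR:s{site:02d}:f{k}" for k in range(1, 6))
    return np.concatenate(vals), names


def encode_disorder(window: PeptideWindow, track) -> tuple[np.ndarray, list[str]]:
    """One disorder score per window site; padded sites score 0."""
    w = window.w
    half = (w - 1) // 2
    L = track.scores.size
    vals = np.zeros(w)
    for i, offset in enumerate(range(-half, half + 1)):
        pos = window.center + offset
        if 1 <= pos <= L:
            vals[i] = track.scores[pos - 1]
    names = [f"DIS:s{site:02d}" for site in range(1, w + 1)]
    return vals, names


def encode_all(
    window: PeptideWindow,
    providers: TrackProvider | None,
    config: EncoderConfig | None = None,
    registry: FeatureRegistry | None = None,
    _factor_table: dict[str, np.ndarray] | None = None,
) -> np.ndarray:
    """Concatenate the enabled families in fixed order AAC, PSSM, FACTOR, DISORDER."""
    if registry is None:
        registry = FeatureRegistry(config or EncoderConfig())
    cfg = registry.config
    parts: list[np.ndarray] = []
    if AAC in cfg.families:
        parts.append(encode_aac(window, cfg.scheme)[0])
    if PSSM in cfg.families:
        if providers is None:
            raise ValueError(f"no PSSM provider configured for {window.protein_id!r}")
        parts.append(encode_pssm(window, providers.get_pssm(window.protein_id), cfg.w)[0])
    if FACTOR in cfg.families:
        parts.append(encode_factors(window, _factor_table)[0])
    if DISORDER in cfg.families:
        if providers is None:
            raise ValueError(
                f"no disorder provider configured for {window.protein_id!r}"
            )
        parts.append(encode_disorder(window, providers.get_disorder(window.protein_id))[0])
    values = np.concatenate(parts) if parts else np.empty(0)
    if values.size != len(registry):
        raise AssertionError("encoded vector misaligned with registry")
    return values


@dataclass
class EncodedDataset:
    """A feature matrix aligned to a registry, with window metadata."""

    X: np.ndarray
    y: np.ndarray
    protein_ids: list[str]
    positions: list[int]
    registry: FeatureRegistry

    @property
    def feature_ids(self) -> list[str]:
        return self.registry.ids

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=self.registry.ids)
        df.insert(0, "protein_id", self.protein_ids)
        df.insert(1, "position", self.positions)
        df.insert(2, "label", np.where(self.y == 1, "positive", "negative"))
        return df

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def subset_rows(self, mask: np.ndarray) -> "EncodedDataset":
        idx = np.asarray(mask)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return EncodedDataset(
            X=self.X[idx],
            y=self.y[idx],
            protein_ids=[self.protein_ids[i] for i in idx],
            positions=[self.positions[i] for i in idx],
            registry=self.registry,
        )


def encode_dataset(
    windows: Sequence[PeptideWindow],
    providers: TrackProvider | None,
    config: EncoderConfig | None = None,
) -> EncodedDataset:
    """Encode every window into one row of a feature matrix."""
    registry = FeatureRegistry(config or EncoderConfig())
    table = load_factor_table() if FACTOR in registry.config.families else None
    X = np.empty((len(windows), len(registry)))
    for i, wdw in enumerate(windows):
        X[i] = encode_all(wdw, providers, registry=registry, _factor_table=table)
    y = np.array([1 if wdw.is_positive else 0 for wdw in windows], dtype=int)
    return EncodedDataset(
        X=X,
        y=y,
        protein_ids=[wdw.protein_id for wdw in windows],
        positions=[wdw.center for wdw in windows],
        registry=registry,
    )


def read_encoded_tsv(path) -> EncodedDataset:
    """Read back a dataset written by :meth:`EncodedDataset.write_tsv`.

    The registry is rebuilt from the default configuration and must match
    the file's feature columns exactly.
    """
    df = pd.read_csv(path, sep="\t")
    meta = ["protein_id", "position", "label"]
    feature_cols = [c for c in df.columns if c not in meta]
    registry = FeatureRegistry(_config_for_columns(feature_cols))
    if feature_cols != registry.ids:
        raise ValueError("feature columns do not match any registry layout")
    return EncodedDataset(
        X=df[feature_cols].to_numpy(float),
        y=(df["label"] == "positive").to_numpy(int),
        protein_ids=df["protein_id"].astype(str).tolist(),
        positions=df["position"].astype(int).tolist(),
        registry=registry,
    )


def _config_for_columns(cols: Iterable[str]) -> EncoderConfig:
    cols = list(cols)
    families = []
    sites = [int(c.split(":")[1][1:]) for c in cols if c.startswith(("PSSM:", "DIS:"))]
    w = max(sites) if sites else 21
    for fam, prefix in ((AAC, "AAC:"), (PSSM, "PSSM:"), (FACTOR, "FACTOR:"), (DISORDER, "DIS:")):
        if any(c.startswith(prefix) for c in cols):
            families.append(fam)
    return EncoderConfig(w=w, families=tuple(families))
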