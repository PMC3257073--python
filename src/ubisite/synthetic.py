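"""Self-contained synthetic benchmarks with known ground truth.

The generator emulates the structure of a curated ubiquitylation corpus —
a few hundred proteins of realistic length, lysines at known positions, a
minority positive class — while planting a controllable class signal in
each feature family:

* a sequence motif: a few flanking window sites prefer a fixed residue in
  positive windows (driving composition and physicochemical-factor
  features);
* surrogate PSSMs: background integer log-odds plus a class-dependent
  shift in chosen (site, column) cells plus noise;
* disorder tracks: smoothed uniform noise plus a bump around positive
  centers.

Surrogate profiles only need the right type, range and a controllable
signal; they are not PSI-BLAST output.  Everything is deterministic given
``SyntheticSpec.seed`` and round-trips through the same file formats the
I/O layer consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .data_io import (
    AMINO_ACIDS,
    NEGATIVE,
    POSITIVE,
    DisorderTrack,
    PeptideWindow,
    ProteinRecord,
    PssmMatrix,
    SiteAnnotation,
    TrackProvider,
    build_windows,
    derive_negative_sites,
)
from .encoders import load_factor_table

#: Default sequence motif: window site -> preferred residue in positives.
DEFAULT_MOTIF: dict[int, str] = {8: "D", 12: "P", 14: "W"}
#: Second PSSM column shifted per motif site (independent of the motif residue).
DEFAULT_PSSM_SECONDARY: dict[int, str] = {8: "E", 12: "G", 14: "Y"}


@dataclass
class SyntheticSpec:
    """Study conditions of the synthetic benchmark.

    Defaults emulate a training corpus of ~300 positive and ~560 negative
    lysines (imbalance about 1:1.9) across 60 proteins, with a strong
    three-site motif around the central lysine of the 21-residue window.
    """

    n_proteins: int = 60
    length_range: tuple[int, int] = (120, 260)
    lysine_density: float = 0.075
    positive_fraction: float = 0.35
    w: int = 21
    motif: Mapping[int, str] = field(default_factory=lambda: dict(DEFAULT_MOTIF))
    motif_strength: float = 0.85
    pssm_shift: float = 4.0
    pssm_noise: float = 1.5
    pssm_secondary: Mapping[int, str] = field(
        default_factory=lambda: dict(DEFAULT_PSSM_SECONDARY)
    )
    disorder_bump: float = 0.35
    disorder_halfwidth: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.positive_fraction < 1.0):
            raise ValueError("positive_fraction must lie in (0, 1)")
        if not (0.0 < self.lysine_density < 1.0):
            raise ValueError("lysine_density must lie in (0, 1)")
        if self.w % 2 == 0:
            raise ValueError("w must be odd")
        center = (self.w + 1) // 2
        for site in self.motif:
            if not (1 <= site <= self.w) or site == center:
                raise ValueError(f"motif site {site} must be a flanking window site")
        if self.length_range[0] < self.w:
            raise ValueError("proteins must be at least one window long")


@dataclass
class GroundTruth:
    """Planted signal: one canonical registry feature per perturbation.

    ``informative_ids`` lists one feature per independently perturbed
    channel: each shifted PSSM cell, each bumped disorder site, and — per
    sequence-motif site — the single factor feature with the largest
    absolute factor value for the preferred residue.  The five factor
    features of one site are deterministic functions of the same residue,
    and the window-aggregated composition features are diluted proxies of
    the same site channels, so neither is counted as an additional
    independent signal.
    """

    informative_ids: list[str]
    site_labels: dict[tuple[str, int], str]


@dataclass
class SyntheticDataset:
    spec: SyntheticSpec
    proteins: list[ProteinRecord]
    annotations: list[SiteAnnotation]
    pssms: dict[str, PssmMatrix]
    disorder: dict[str, DisorderTrack]
    ground_truth: GroundTruth

    def provider(self) -> TrackProvider:
        return TrackProvider(pssms=self.pssms, disorder=self.disorder)

    def windows(self) -> list[PeptideWindow]:
        return build_windows(self.proteins, self.annotations, w=self.spec.w)

    @property
    def n_positive(self) -> int:
        return sum(a.is_positive for a in self.annotations)

    @property
    def n_negative(self) -> int:
        return sum(not a.is_positive for a in self.annotations)


def _canonical_factor_id(site: int, residue: str) -> str:
    table = load_factor_table()
    k = int(np.argmax(np.abs(table[residue]))) + 1
    return f"FACTOR:s{site:02d}:f{k}"


def _ground_truth_ids(spec: SyntheticSpec) -> list[str]:
    ids: list[str] = []
    for site in sorted(spec.motif):
        r = spec.motif[site]
        ids.append(_canonical_factor_id(site, r))
        if spec.pssm_shift > 0:
            ids.append(f"PSSM:s{site:02d}:{r}")
            sec = spec.pssm_secondary.get(site)
            if sec is not None:
                ids.append(f"PSSM:s{site:02d}:{sec}")
    if spec.disorder_bump > 0:
        center = (spec.w + 1) // 2
        for site in range(
            center - spec.disorder_halfwidth, center + spec.disorder_halfwidth + 1
        ):
            ids.append(f"DIS:s{site:02d}")
    return ids


def generate_dataset(spec: SyntheticSpec | None = None) -> SyntheticDataset:
    """Draw one complete benchmark from the spec; all randomness flows from the seed."""
    spec = spec or SyntheticSpec()
    rng = np.random.default_rng(spec.seed)
    non_k = [aa for aa in AMINO_ACIDS if aa != "K"]
    center = (spec.w + 1) // 2

    sequences: dict[str, list[str]] = {}
    all_lysines: list[tuple[str, int]] = []
    for i in range(spec.n_proteins):
        pid = f"synth{i:04d}"
        L = int(rng.integers(spec.length_range[0], spec.length_range[1] + 1))
        is_k = rng.random(L) < spec.lysine_density
        background = rng.choice(list(non_k), size=L)
        seq = [("K" if k else aa) for k, aa in zip(is_k, background)]
        sequences[pid] = seq
        all_lysines.extend((pid, p + 1) for p in range(L) if seq[p] == "K")

    if not all_lysines:
        raise ValueError("infeasible spec: no lysines were generated")
    order = rng.permutation(len(all_lysines))
    n_pos = max(1, round(spec.positive_fraction * len(all_lysines)))
    positive_keys = {all_lysines[j] for j in order[:n_pos]}

    # plant the sequence motif in the flanks of positive sites, never
    # overwriting another positive center
    offsets = {site: site - center for site in spec.motif}
    for pid, pos in sorted(positive_keys):
        seq = sequences[pid]
        for site, residue in spec.motif.items():
            p = pos + offsets[site]  # 1-based
            if not (1 <= p <= len(seq)) or (pid, p) in positive_keys:
                continue
            if rng.random() < spec.motif_strength:
                seq[p - 1] = residue

    proteins = [
        ProteinRecord(id=pid, sequence="".join(seq)) for pid, seq in sequences.items()
    ]
    # rewriting may delete lysines; keep only positives whose center survived
    positives = [
        SiteAnnotation(protein_id=pid, position=pos, label=POSITIVE)
        for pid, pos in sorted(positive_keys)
        if sequences[pid][pos - 1] == "K"
    ]
    negatives = derive_negative_sites(proteins, positives)
    annotations = sorted(
        positives + negatives, key=lambda a: (a.protein_id, a.position)
    )

    aa_index = {aa: j for j, aa in enumerate(AMINO_ACIDS)}
    pos_by_protein: dict[str, list[int]] = {}
    for a in positives:
        pos_by_protein.setdefault(a.protein_id, []).append(a.position)

    pssms: dict[str, PssmMatrix] = {}
    disorder: dict[str, DisorderTrack] = {}
    for prot in proteins:
        L = prot.length
        raw = np.round(rng.normal(0.0, 2.0, size=(L, 20)))
        for pos in pos_by_protein.get(prot.id, []):
            for site in spec.motif:
                p = pos + offsets[site]
                if not (1 <= p <= L):
                    continue
                cols = [aa_index[spec.motif[site]]]
                sec = spec.pssm_secondary.get(site)
                if sec is not None:
                    cols.append(aa_index[sec])
                for c in cols:
                    raw[p - 1, c] += np.round(
                        spec.pssm_shift + rng.normal(0.0, spec.pssm_noise)
                    )
        pssms[prot.id] = PssmMatrix(protein_id=prot.id, raw=raw)

        base = np.convolve(rng.random(L), np.ones(3) / 3.0, mode="same")
        for pos in pos_by_protein.get(prot.id, []):
            lo = max(0, pos - 1 - spec.disorder_halfwidth)
            hi = min(L, pos + spec.disorder_halfwidth)
            base[lo:hi] += spec.disorder_bump
        disorder[prot.id] = DisorderTrack(protein_id=prot.id, scores=base)

    truth = GroundTruth(
        informative_ids=_ground_truth_ids(spec),
        site_labels={(a.protein_id, a.position): a.label for a in annotations},
    )
    return SyntheticDataset(
        spec=spec,
        proteins=proteins,
        annotations=annotations,
        pssms=pssms,
        disorder=disorder,
        ground_truth=truth,
    )


def make_null_permutation(dataset: SyntheticDataset, seed: int) -> SyntheticDataset:
    """Permute site labels within each protein; features stay untouched.

    A negative control: any pipeline run on the permuted dataset should
    perform at chance level.
    """
    if not dataset.annotations:
        raise ValueError("empty dataset")
    rng = np.random.default_rng(seed)
    permuted: list[SiteAnnotation] = []
    by_protein: dict[str, list[SiteAnnotation]] = {}
    for a in dataset.annotations:
        by_protein.setdefault(a.protein_id, []).append(a)
    for pid in sorted(by_protein):
        anns = by_protein[pid]
        labels = [a.label for a in anns]
        shuffled = [labels[j] for j in rng.permutation(len(labels))]
        for a, lab in zip(anns, shuffled):
            permuted.append(
                SiteAnnotation(protein_id=a.protein_id, position=a.position, label=lab)
            )
    permuted.sort(key=lambda a: (a.protein_id, a.position))
    truth = GroundTruth(
        informative_ids=list(dataset.ground_truth.informative_ids),
        site_labels={(a.protein_id, a.position): a.label for a in permuted},
    )
    return SyntheticDataset(
        spec=dataset.spec,
        proteins=dataset.proteins,
        annotations=permuted,
        pssms=dataset.pssms,
        disorder=dataset.disorder,
        ground_truth=truth,
    )


# ---------------------------------------------------------------------------
# file emission (formats consumed by data_io)
# ---------------------------------------------------------------------------

def write_dataset(dataset: SyntheticDataset, outdir: str | Path) -> None:
    """Emit FASTA, annotation TSV, per-protein .pssm / .disorder.tsv, ground truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "proteins.fasta", "w") as fh:
        for prot in dataset.proteins:
            fh.write(f">{prot.id}\n")
            for i in range(0, prot.length, 60):
                fh.write(prot.sequence[i : i + 60] + "\n")
    pd.DataFrame(
        {
            "protein_id": [a.protein_id for a in dataset.annotations],
            "position": [a.position for a in dataset.annotations],
            "label": [a.label for a in dataset.annotations],
        }
    ).to_csv(outdir / "annotations.tsv", sep="\t", index=False)
    for pid, pssm in dataset.pssms.items():
        _write_pssm_ascii(pssm, dataset, outdir / f"{pid}.pssm")
    for pid, track in dataset.disorder.items():
        pd.DataFrame(
            {"position": np.arange(1, track.length + 1), "score": track.scores}
        ).to_csv(outdir / f"{pid}.disorder.tsv", sep="\t", index=False)
    pd.DataFrame({"feature_id": dataset.ground_truth.informative_ids}).to_csv(
        outdir / "ground_truth.tsv", sep="\t", index=False
    )


def _write_pssm_ascii(pssm: PssmMatrix, dataset: SyntheticDataset, path: Path) -> None:
    seq = next(p.sequence for p in dataset.proteins if p.id == pssm.protein_id)
    with open(path, "w") as fh:
        fh.write("\nLast position-specific scoring matrix computed\n")
        fh.write("   " + "  ".join(AMINO_ACIDS) + "\n")
        for i, row in enumerate(pssm.raw.astype(int), start=1):
            fh.write(f"{i:5d} {seq[i - 1]} " + " ".join(f"{v:3d}" for v in row) + "\n")
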