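"""Seeded synthetic generator of paired hyb + Vienna files with ground truth.

Stands in for qCLASH-style chimeric datasets in tests and demos: each
generated record is a two-segment hybrid read with a matched Vienna fold
record and a ground-truth row (segment types, miRNA placement, read count,
per-nucleotide bound vector). Generation is a pure function of
(spec, seed): a single seeded pseudo-random stream drives every choice, so
one integer reproduces a dataset byte-for-byte.

The duplex model is deliberately simple and synthetic: a contiguous block
of b bound positions is placed at a seeded offset within the miRNA, with
the matching block on the target side, and a pseudo-energy of
``-(0.5 * b) + Uniform(-0.5, 0.5)`` kcal/mol. It exists to exercise
plumbing and weighted statistics, not thermodynamics; no read-error,
adapter, or PCR-duplicate modeling is attempted.
"""

from __future__ import annotations

import os
import random
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .errors import ConfigurationError
from .fold import FoldRecord, write_vienna_record
from .hyb_io import write_hyb_line
from .hyb_model import FlagTable, HybRecord, SegmentInfo

_DNA = "ACGT"
_RNA_OF = str.maketrans("T", "U")

DEFECTS = ("field-count", "bad-coordinate", "unbalanced-fold", "seq-mismatch")


def _canonical(type_str: str) -> str:
    return "miRNA" if type_str == "microRNA" else type_str


def _random_seq(rng: random.Random, length: int) -> str:
    return "".join(rng.choice(_DNA) for _ in range(length))


def _build_default_pools() -> tuple[tuple, tuple]:
    """Deterministic reference pools: 6 miRNAs (18-22 nt) with Hyb-style
    4-part ids ending ``_microRNA``, and mRNA/lncRNA/rRNA targets
    (20-40 nt)."""
    rng = random.Random(20240901)
    mirnas = []
    for i, length in enumerate((18, 19, 20, 21, 22, 20), start=1):
        name = f"MIMAT{i:07d}_mirbase_hsa-miR-{i}-5p_microRNA"
        mirnas.append((name, _random_seq(rng, length)))
    targets = []
    for i in range(1, 7):
        name = f"ENSG{i:08d}_ENST{i:08d}_GENE{chr(64 + i)}_mRNA"
        targets.append((name, _random_seq(rng, rng.randint(20, 40))))
    for i in range(1, 4):
        name = f"ENSG{i + 100:08d}_ENST{i + 100:08d}_LINC{i:04d}_lncRNA"
        targets.append((name, _random_seq(rng, rng.randint(20, 40))))
    for i in range(1, 3):
        name = f"RF{i:05d}_rfam_LSU-rRNA-{i}_rRNA"
        targets.append((name, _random_seq(rng, rng.randint(20, 40))))
    return tuple(mirnas), tuple(targets)


DEFAULT_MIRNA_POOL, DEFAULT_TARGET_POOL = _build_default_pools()


@dataclass(frozen=True)
class FixtureSpec:
    """Generation parameters with study-condition defaults.

    ``type_mixture`` gives target-type probabilities for the non-miRNA
    segment; ``placement_mixture`` gives probabilities over miRNA
    placements (5p/3p/B/N); ``count_geometric_p`` parameterizes the
    geometric read-count distribution (support ≥ 1); ``bound_range``
    bounds the number of base-paired miRNA positions b (uniform);
    ``mismatch_rate`` injects negative-control fold records whose
    sequence differs from the hyb sequence at one base.
    """

    n_records: int = 100
    seed: int = 42
    mirna_pool: Sequence[tuple[str, str]] = DEFAULT_MIRNA_POOL
    target_pool: Sequence[tuple[str, str]] = DEFAULT_TARGET_POOL
    type_mixture: Mapping[str, float] = field(
        default_factory=lambda: {"mRNA": 0.6, "lncRNA": 0.3, "rRNA": 0.1})
    placement_mixture: Mapping[str, float] = field(
        default_factory=lambda: {"5p": 0.4, "3p": 0.2, "B": 0.1, "N": 0.3})
    count_geometric_p: float = 0.5
    bound_range: tuple[int, int] = (4, 12)
    mismatch_rate: float = 0.0

    def validated(self) -> "FixtureSpec":
        if not self.mirna_pool or not self.target_pool:
            raise ConfigurationError("reference pools must be non-empty")
        for name, mixture in (("type_mixture", self.type_mixture),
                              ("placement_mixture", self.placement_mixture)):
            total = sum(mixture.values())
            if abs(total - 1.0) > 1e-9 or any(v < 0 for v in mixture.values()):
                raise ConfigurationError(
                    f"{name} must be non-negative and sum to 1 (got {total})")
        if not 0.0 < self.count_geometric_p <= 1.0:
            raise ConfigurationError("count_geometric_p must be in (0, 1]")
        lo, hi = self.bound_range
        if lo < 1 or hi < lo:
            raise ConfigurationError("invalid bound_range")
        return self

    def _type_of(self, name: str) -> str:
        return name.rsplit("_", 1)[-1]

    def targets_of_type(self, type_str: str) -> list[tuple[str, str]]:
        return [(n, s) for n, s in self.target_pool
                if self._type_of(n) == type_str]


@dataclass
class FixtureSet:
    """Generated records plus their ground-truth table."""

    spec: FixtureSpec
    hyb_records: list[HybRecord]
    fold_records: list[FoldRecord]
    truth: pd.DataFrame

    def hyb_text(self) -> str:
        return "".join(write_hyb_line(r) + "\n" for r in self.hyb_records)

    def vienna_text(self) -> str:
        return "".join("\n".join(write_vienna_record(r)) + "\n"
                       for r in self.fold_records)

    def write(self, out_dir: str | os.PathLike,
              prefix: str = "fixture") -> tuple[str, str, str]:
        """Write <prefix>.hyb, <prefix>.vienna, <prefix>.truth.tsv."""
        os.makedirs(out_dir, exist_ok=True)
        hyb_path = os.path.join(out_dir, f"{prefix}.hyb")
        vienna_path = os.path.join(out_dir, f"{prefix}.vienna")
        truth_path = os.path.join(out_dir, f"{prefix}.truth.tsv")
        with open(hyb_path, "w", encoding="utf-8", newline="") as out:
            out.write(self.hyb_text())
        with open(vienna_path, "w", encoding="utf-8", newline="") as out:
            out.write(self.vienna_text())
        self.truth.to_csv(truth_path, sep="\t", index=False)
        return hyb_path, vienna_path, truth_path


def _geometric(rng: random.Random, p: float) -> int:
    count = 1
    while rng.random() >= p:
        count += 1
    return count


def _weighted_choice(rng: random.Random, mixture: Mapping[str, float]) -> str:
    items = list(mixture.items())
    return rng.choices([k for k, _ in items], weights=[w for _, w in items],
                       k=1)[0]


def generate(spec: FixtureSpec) -> FixtureSet:
    """Generate record-aligned hyb and Vienna records with ground truth.

    The k-th hyb record corresponds to the k-th fold record; the read
    sequence is the concatenation of the two segment sequences; the
    dot-bracket encodes exactly the truth table's bound positions, with
    ``(`` on the 5' member of the duplex and matching ``)`` on the 3'
    member (balanced by construction). B- and N-placement records carry
    an unpaired (all-dot) fold.
    """
    spec = spec.validated()
    rng = random.Random(spec.seed)
    hyb_records: list[HybRecord] = []
    fold_records: list[FoldRecord] = []
    truth_rows = []
    for k in range(1, spec.n_records + 1):
        rec_id = f"R{k:06d}"
        placement = _weighted_choice(rng, spec.placement_mixture)
        if placement in ("5p", "3p"):
            mirna = rng.choice(list(spec.mirna_pool))
            target_type = _weighted_choice(rng, spec.type_mixture)
            candidates = spec.targets_of_type(target_type)
            if not candidates:
                raise ConfigurationError(
                    f"no targets of type {target_type!r} in pool")
            target = rng.choice(candidates)
            if placement == "5p":
                (name1, seq1), (name2, seq2) = mirna, target
            else:
                (name1, seq1), (name2, seq2) = target, mirna
        elif placement == "B":
            pair = rng.sample(list(spec.mirna_pool), 2)
            (name1, seq1), (name2, seq2) = pair
        else:  # N
            t1 = _weighted_choice(rng, spec.type_mixture)
            t2 = _weighted_choice(rng, spec.type_mixture)
            (name1, seq1) = rng.choice(spec.targets_of_type(t1))
            (name2, seq2) = rng.choice(spec.targets_of_type(t2))
        len1, len2 = len(seq1), len(seq2)
        seq = seq1 + seq2
        count = _geometric(rng, spec.count_geometric_p)

        # duplex model: contiguous bound block within the miRNA, mirrored
        # on the target side; pseudo-energy from the block size
        fold_chars = ["."] * len(seq)
        bound_vec = ""
        if placement in ("5p", "3p"):
            mirna_len = len(mirna[1])
            target_len = len(target[1])
            b = rng.randint(*spec.bound_range)
            b = min(b, mirna_len, target_len)
            mirna_off = rng.randint(0, mirna_len - b)
            target_off = rng.randint(0, target_len - b)
            if placement == "5p":
                open_lo = mirna_off               # within seg1
                close_lo = len1 + target_off      # within seg2
            else:
                open_lo = target_off              # target is seg1
                close_lo = len1 + mirna_off       # miRNA is seg2
            for i in range(b):
                fold_chars[open_lo + i] = "("
                fold_chars[close_lo + i] = ")"
            vec = [False] * mirna_len
            for i in range(b):
                vec[mirna_off + i] = True
            bound_vec = "".join("1" if x else "0" for x in vec)
            energy = -(0.5 * b) + rng.uniform(-0.5, 0.5)
        else:
            energy = rng.uniform(-0.5, 0.5)
        energy_token = f"{energy:.1f}"

        seg1 = SegmentInfo(ref_name=name1, read_start=1, read_end=len1,
                           ref_start=1, ref_end=len1, score="0.001")
        seg2 = SegmentInfo(ref_name=name2, read_start=len1 + 1,
                           read_end=len1 + len2, ref_start=1, ref_end=len2,
                           score="0.001")
        flags = FlagTable([("count_total", str(count)),
                           ("read_count", str(count))])
        hyb_records.append(HybRecord(id=rec_id, seq=seq, seg1=seg1,
                                     seg2=seg2, energy=energy_token,
                                     flags=flags))

        vienna_seq = seq.translate(_RNA_OF)
        mismatched = False
        if spec.mismatch_rate > 0 and rng.random() < spec.mismatch_rate:
            pos = rng.randrange(len(vienna_seq))
            alternatives = [c for c in "ACGU" if c != vienna_seq[pos]]
            vienna_seq = (vienna_seq[:pos] + rng.choice(alternatives)
                          + vienna_seq[pos + 1:])
            mismatched = True
        fold_records.append(FoldRecord(id=rec_id, seq=vienna_seq,
                                       fold="".join(fold_chars),
                                       energy=energy_token))
        # canonical types (microRNA -> miRNA), matching evaluated output
        truth_rows.append({
            "id": rec_id,
            "seg1_type": _canonical(spec._type_of(name1)),
            "seg2_type": _canonical(spec._type_of(name2)),
            "placement": placement,
            "count_total": count,
            "bound_vector": bound_vec,
            "seg1_name": name1,
            "seg2_name": name2,
            "energy": energy_token,
            "fold_mismatch": int(mismatched),
        })
    truth = pd.DataFrame(truth_rows)
    return FixtureSet(spec=spec, hyb_records=hyb_records,
                      fold_records=fold_records, truth=truth)


def generate_malformed(spec: FixtureSpec, defect: str,
                       positions: Sequence[int] | None = None,
                       ) -> tuple[list[str], list[str], list[dict]]:
    """Generate a fixture and inject one defect kind at known records.

    ``positions`` are 1-based record indices (default: the middle record).
    Returns (hyb lines, vienna record line-triples flattened, manifest);
    the manifest lists exactly the defective records — all others are
    clean.
    """
    if defect not in DEFECTS:
        raise ConfigurationError(
            f"unsupported defect {defect!r}; expected one of {DEFECTS}")
    data = generate(spec)
    n = spec.n_records
    if positions is None:
        positions = [max(1, (n + 1) // 2)]
    for pos in positions:
        if not 1 <= pos <= n:
            raise ConfigurationError(f"defect position {pos} out of range")
    hyb_lines = [write_hyb_line(r) for r in data.hyb_records]
    vienna_lines: list[str] = []
    for r in data.fold_records:
        vienna_lines.extend(write_vienna_record(r))
    manifest = []
    for pos in positions:
        idx = pos - 1
        if defect == "field-count":
            hyb_lines[idx] = "\t".join(hyb_lines[idx].split("\t")[:-2])
        elif defect == "bad-coordinate":
            fields = hyb_lines[idx].split("\t")
            fields[5] = "NA"  # seg1.read_end
            hyb_lines[idx] = "\t".join(fields)
        elif defect == "unbalanced-fold":
            line_idx = idx * 3 + 2
            fold_line = vienna_lines[line_idx]
            # replacing the final structure char with '(' leaves the
            # running balance positive at end-of-string
            if "\t" in fold_line:
                struct, rest = fold_line.split("\t", 1)
                vienna_lines[line_idx] = struct[:-1] + "(" + "\t" + rest
            else:
                vienna_lines[line_idx] = fold_line[:-1] + "("
        else:  # seq-mismatch
            line_idx = idx * 3 + 1
            seq = vienna_lines[line_idx]
            alternatives = [c for c in "ACGU" if c != seq[0]]
            vienna_lines[line_idx] = alternatives[0] + seq[1:]
        manifest.append({"defect": defect, "record_index": pos,
                         "hyb_line": pos, "vienna_record": pos})
    return hyb_lines, vienna_lines, manifest


def write_malformed(spec: FixtureSpec, defect: str,
                    out_dir: str | os.PathLike, prefix: str = "defective",
                    positions: Sequence[int] | None = None,
                    ) -> tuple[str, str, str]:
    """File-writing convenience around :func:`generate_malformed`."""
    hyb_lines, vienna_lines, manifest = generate_malformed(
        spec, defect, positions)
    os.makedirs(out_dir, exist_ok=True)
    hyb_path = os.path.join(out_dir, f"{prefix}.hyb")
    vienna_path = os.path.join(out_dir, f"{prefix}.vienna")
    manifest_path = os.path.join(out_dir, f"{prefix}.manifest.tsv")
    with open(hyb_path, "w", encoding="utf-8", newline="") as out:
        out.write("\n".join(hyb_lines) + "\n")
    with open(vienna_path, "w", encoding="utf-8", newline="") as out:
        out.write("\n".join(vienna_lines) + "\n")
    pd.DataFrame(manifest).to_csv(manifest_path, sep="\t", index=False)
    return hyb_path, vienna_path, manifest_path
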