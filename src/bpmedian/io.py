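"""Reading and writing genomes and analysis reports.

Genome text dialect (GRIMM-like, unsigned, single chromosome): one genome
per line as whitespace-separated integer labels ``1..n``; lines starting
with ``#`` are comments; an optional ``>name`` line names the genome that
follows.  Parse -> write -> parse round-trips exactly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence, Union

from .extremal_sets import max_distant_set, nongeodesic_pair
from .genome_core import (
    GenomeClass,
    GenomeInputError,
    Permutation,
)

__all__ = ["GenomeFile", "read_genomes", "parse_genomes", "write_genomes", "write_report", "make_fixtures"]

#: The worked six-gene geodesic: each step cuts/rejoins one adjacency, the
#: i-th genome is at distance i from the first and 5-i from the last.
EXAMPLE_GEODESIC_6 = (
    "1 2 3 4 5 6",
    "2 1 3 4 5 6",
    "3 1 2 4 5 6",
    "4 2 1 3 5 6",
    "5 3 1 2 4 6",
    "1 3 5 2 4 6",
)


@dataclass(frozen=True)
class GenomeFile:
    """An ordered collection of named genomes of a common length."""

    path: str | None
    genomes: tuple[tuple[str, Permutation], ...]

    @property
    def n(self) -> int:
        return self.genomes[0][1].n

    def permutations(self) -> tuple[Permutation, ...]:
        return tuple(p for _, p in self.genomes)

    def classes(self) -> tuple[GenomeClass, ...]:
        return tuple(GenomeClass(p) for _, p in self.genomes)

    def __len__(self) -> int:
        return len(self.genomes)


def parse_genomes(text: str, path: str | None = None) -> GenomeFile:
    """Parse the genome dialect from a string; see the module docstring."""
    genomes: list[tuple[str, Permutation]] = []
    pending_name: str | None = None
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith(">"):
            if pending_name is not None:
                raise GenomeInputError(
                    f"line {lineno}: name line {line!r} follows another name "
                    "line with no genome between them"
                )
            pending_name = line[1:].strip() or f"genome{len(genomes) + 1}"
            continue
        try:
            genes = [int(tok) for tok in line.split()]
        except ValueError as exc:
            bad = next(tok for tok in line.split() if not tok.lstrip("-").isdigit())
            raise GenomeInputError(
                f"line {lineno}: non-integer token {bad!r}"
            ) from exc
        try:
            perm = Permutation(genes)
        except GenomeInputError as exc:
            raise GenomeInputError(f"line {lineno}: {exc}") from exc
        name = pending_name or f"genome{len(genomes) + 1}"
        pending_name = None
        genomes.append((name, perm))
    if pending_name is not None:
        raise GenomeInputError(f"trailing name line {pending_name!r} with no genome")
    if not genomes:
        raise GenomeInputError("no genomes found")
    lengths = {p.n for _, p in genomes}
    if len(lengths) != 1:
        raise GenomeInputError(f"mixed genome lengths {sorted(lengths)}")
    return GenomeFile(path=path, genomes=tuple(genomes))


def read_genomes(path: str | Path) -> GenomeFile:
    path = Path(path)
    return parse_genomes(path.read_text(), path=str(path))


def write_genomes(
    genomes: Union[GenomeFile, Iterable], path: str | Path, names: Sequence[str] | None = None
) -> None:
    """Write genomes in the same dialect ``read_genomes`` parses."""
    path = Path(path)
    if isinstance(genomes, GenomeFile):
        pairs = genomes.genomes
    else:
        items = list(genomes)
        if names is None:
            names = [f"genome{i + 1}" for i in range(len(items))]
        pairs = []
        for name, g in zip(names, items):
            if isinstance(g, GenomeClass):
                g = g.representative
            pairs.append((name, g))
    lines = []
    for name, perm in pairs:
        lines.append(f">{name}")
        lines.append(str(perm))
    path.write_text("\n".join(lines) + "\n")


def _jsonable(obj):
    from .median import ConjectureReport, MedianResult
    from .random_sim import SimReport

    if isinstance(obj, MedianResult):
        return {
            "value": obj.value,
            "n_medians": obj.n_medians,
            "method": obj.method,
            "medians": sorted(str(m) for m in obj.medians),
        }
    if isinstance(obj, ConjectureReport):
        out = obj.summary()
        out["missing"] = sorted(str(m) for m in obj.missing)
        return out
    if isinstance(obj, SimReport):
        return obj.summary()
    if dataclasses.is_dataclass(obj):
        return dataclasses.asdict(obj)
    raise TypeError(f"cannot serialize {type(obj).__name__}")


def write_report(result, format: str, path: str | Path) -> None:
    """Serialize a solver/simulator result to JSON or TSV.

    JSON carries the scalar summary (plus median lists where applicable);
    TSV of a simulation report is its per-replicate table.
    """
    from .random_sim import SimReport

    path = Path(path)
    if format == "json":
        path.write_text(json.dumps(_jsonable(result), indent=2) + "\n")
    elif format == "tsv":
        if isinstance(result, SimReport) and len(result.replicates):
            result.replicates.to_csv(path, sep="\t", index=False)
        else:
            obj = _jsonable(result)
            lines = ["key\tvalue"] + [f"{k}\t{v}" for k, v in obj.items()]
            path.write_text("\n".join(lines) + "\n")
    else:
        raise ValueError(f"unknown report format {format!r}")


def make_fixtures(outdir: str | Path, seed: int = 0) -> dict[str, Path]:
    """Write the small worked-example inputs used throughout the docs/tests.

    Emits the maximally distant six-gene pair and its geodesic chain, a
    seven-gene pair with no geodesic, a maximally distant (n=7, k=3) set,
    and a small random genome collection; reproducible for a fixed seed.
    """
    import numpy as np

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    out: dict[str, Path] = {}

    chain = [Permutation.from_string(s) for s in EXAMPLE_GEODESIC_6]
    out["eq6_pair"] = outdir / "maxdist_pair_n6.txt"
    write_genomes([chain[0], chain[-1]], out["eq6_pair"], names=["id6", "interleaved"])
    out["eq6_chain"] = outdir / "geodesic_chain_n6.txt"
    write_genomes(chain, out["eq6_chain"], names=[f"step{i}" for i in range(len(chain))])

    ng = nongeodesic_pair(7, (4, 3, 5))
    out["nongeodesic_pair"] = outdir / "nongeodesic_pair_n7.txt"
    write_genomes(list(ng), out["nongeodesic_pair"], names=["id7", "blocked"])

    mds = max_distant_set(7, 3, seed=seed)
    out["maxdist_7_3"] = outdir / "maxdist_n7_k3.txt"
    write_genomes(list(mds), out["maxdist_7_3"], names=[f"x{i + 1}" for i in range(3)])

    rng = np.random.Generator(np.random.PCG64(seed))
    randoms = [Permutation(rng.permutation(6) + 1) for _ in range(4)]
    out["random_n6"] = outdir / "random_n6_k4.txt"
    write_genomes(randoms, out["random_n6"], names=[f"r{i + 1}" for i in range(4)])
    return out
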