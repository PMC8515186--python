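"""Reading and writing the pipeline's plain-text formats.

All tables are TSV.  Genotype matrices are written with markers as rows (in
map order) and individuals as columns, calls coded ``A``/``B``/``H``/``NA``.
Writers prepend ``#``-comment header lines naming the software version and a
hash of the generating configuration, so every artifact is traceable;
readers skip ``#`` lines.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .core import CODE_TO_TOKEN, MISSING, TOKEN_TO_CODE, GenotypeMatrix, MarkerMap


def config_hash(config: dict | None) -> str:
    payload = json.dumps(config or {}, sort_keys=True, default=str)
    return hashlib.sha1(payload.encode()).hexdigest()[:12]


def header_lines(config: dict | None = None) -> str:
    return f"# recland v{__version__} config={config_hash(config)}\n"


def _write_tsv(df: pd.DataFrame, path, config: dict | None = None) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(header_lines(config))
        df.to_csv(fh, sep="\t", index=False)


def write_table(df: pd.DataFrame, path, config: dict | None = None) -> None:
    """Generic TSV writer with the version/config-hash header."""
    _write_tsv(df, path, config)


# ---------------------------------------------------------------------------
# marker maps
# ---------------------------------------------------------------------------

def write_marker_map(mm: MarkerMap, path, config: dict | None = None) -> None:
    _write_tsv(mm.table, path, config)


def read_marker_map(path) -> MarkerMap:
    tab = pd.read_csv(path, sep="\t", comment="#", dtype={"marker": str, "chrom": str})
    return MarkerMap(tab)


# ---------------------------------------------------------------------------
# genotype matrices
# ---------------------------------------------------------------------------

def write_genotypes(gm: GenotypeMatrix, path, config: dict | None = None) -> None:
    codes = np.vectorize(CODE_TO_TOKEN.get)(gm.calls)
    df = pd.DataFrame(codes, columns=gm.individuals)
    df.insert(0, "marker", gm.marker_ids)
    _write_tsv(df, path, config)


def read_genotypes(genotype_path, map_path) -> tuple[GenotypeMatrix, MarkerMap]:
    """Read a genotype TSV plus marker map; sort markers by (chrom, pos).

    Unrecognised call tokens are coerced to MISSING with a single warning
    reporting the count.  A genotype marker absent from the map, or a
    duplicated individual id, is a hard error.
    """
    mm = read_marker_map(map_path).sorted()

    # detect duplicated individual columns before pandas mangles them
    with open(genotype_path) as fh:
        for line in fh:
            if not line.startswith("#"):
                header = line.rstrip("\n").split("\t")
                break
        else:
            raise ValueError(f"{genotype_path}: empty file")
    ind_ids = header[1:]
    if len(set(ind_ids)) != len(ind_ids):
        dups = sorted({i for i in ind_ids if ind_ids.count(i) > 1})
        raise ValueError(f"duplicated individual ids in {genotype_path}: {dups}")

    df = pd.read_csv(
        genotype_path, sep="\t", comment="#", dtype=str, keep_default_na=False, na_values=[]
    )
    markers = df.iloc[:, 0].tolist()
    known = set(mm.marker_ids)
    orphans = [m for m in markers if m not in known]
    if orphans:
        raise ValueError(f"markers absent from map: {orphans[:10]}")

    tokens = df.iloc[:, 1:].to_numpy(dtype=object)
    codes = np.full(tokens.shape, MISSING, dtype=np.int8)
    unknown = 0
    for tok, code in TOKEN_TO_CODE.items():
        codes[tokens == tok] = code
    recognised = np.isin(tokens, list(TOKEN_TO_CODE))
    unknown = int((~recognised).sum())
    if unknown:
        warnings.warn(
            f"{unknown} unrecognised call token(s) coerced to MISSING", UserWarning
        )

    gm = GenotypeMatrix(codes, markers, ind_ids)
    mm = mm.subset(markers)  # drop map-only markers, keep analysis order
    if len(mm.table) < len(known):
        warnings.warn(
            f"{len(known) - len(mm.table)} map marker(s) absent from genotype file; dropped",
            UserWarning,
        )
    return gm.align_to(mm), mm


# ---------------------------------------------------------------------------
# crossover tables, interval tables
# ---------------------------------------------------------------------------

def write_crossovers(co: pd.DataFrame, path, config: dict | None = None) -> None:
    _write_tsv(co, path, config)


def read_crossovers(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype={"individual": str, "chrom": str})


def write_intervals(intervals: pd.DataFrame, path, config: dict | None = None) -> None:
    _write_tsv(intervals, path, config)


def crossovers_to_bed(co: pd.DataFrame) -> pd.DataFrame:
    """CO intervals as BED (0-based half-open) from 1-based inclusive bp."""
    return pd.DataFrame(
        {
            "chrom": co["chrom"],
            "start": co["left_bp"].astype(int) - 1,
            "end": co["right_bp"].astype(int),
            "name": co["individual"],
            "score": co["score"],
        }
    )


def intervals_to_bedgraph(intervals: pd.DataFrame, path) -> None:
    """Per-interval cM as BEDGRAPH for genome-browser viewing."""
    bg = pd.DataFrame(
        {
            "chrom": intervals["chrom"],
            "start": intervals["left_bp"].astype(int) - 1,
            "end": intervals["right_bp"].astype(int),
            "value": intervals["cm"].fillna(0.0),
        }
    )
    bg.to_csv(path, sep="\t", index=False, header=False)


# ---------------------------------------------------------------------------
# truth records (simulation ground truth), JSON lines
# ---------------------------------------------------------------------------

def write_truth(truths, path) -> None:
    with open(path, "w") as fh:
        for t in truths:
            fh.write(
                json.dumps(
                    {
                        "individual": t.individual,
                        "gamete": t.gamete,
                        "chrom": t.chrom,
                        "positions": list(map(float, t.positions)),
                    }
                )
                + "\n"
            )


def read_truth(path):
    from .simulate import TruthRecord

    out = []
    with open(path) as fh:
        for line in fh:
            d = json.loads(line)
            out.append(
                TruthRecord(
                    individual=d["individual"],
                    gamete=d["gamete"],
                    chrom=d["chrom"],
                    positions=np.asarray(d["positions"], dtype=float),
                )
            )
    return out
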