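"""Readers and writers for the pipeline's plain-text formats.

Expression matrices, dosage matrices and trait tables are tab-separated
with labelled header rows; genotypes can also round-trip through VCF (GT
field, dosages re-coded to count the minor allele on read). Ground-truth
records and QC reports serialize to JSON. All coordinates are 1-based.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import ExpressionDataset, GenotypeDataset, TraitTable

__all__ = [
    "read_expression",
    "write_expression",
    "read_genotypes",
    "write_genotypes",
    "read_traits",
    "write_traits",
    "write_truth",
    "read_truth",
]

_ANNOT_COLS = ["chromosome", "position", "globin", "n_mappings"]


def _check_duplicate_header(path: Path) -> None:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    seen = set()
    for name in header:
        if name in seen:
            raise ValueError(f"duplicate column {name!r} in {path}")
        seen.add(name)


def read_expression(path) -> ExpressionDataset:
    """Read a probes x samples TSV (probe id column + optional annotation
    columns chromosome/position/globin/n_mappings, then sample columns)."""
    path = Path(path)
    _check_duplicate_header(path)
    df = pd.read_csv(path, sep="\t", dtype={"chromosome": str})
    if "probe" not in df.columns:
        raise ValueError(f"{path}: missing 'probe' column")
    if df["probe"].duplicated().any():
        dup = df["probe"][df["probe"].duplicated()].iloc[0]
        raise ValueError(f"{path}: duplicate probe id {dup!r}")
    df = df.set_index("probe")
    ann_cols = [c for c in _ANNOT_COLS if c in df.columns]
    annotations = df[ann_cols].copy() if ann_cols else None
    values = df.drop(columns=ann_cols)
    bad = values.map(lambda v: not isinstance(v, (int, float, np.number)))
    if bad.any().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"{path}: non-numeric value at probe {values.index[i]!r}, "
            f"sample {values.columns[j]!r}"
        )
    if annotations is None:
        warnings.warn(f"{path}: no annotation columns; probe filters unavailable")
    else:
        if "globin" in annotations:
            annotations["globin"] = annotations["globin"].astype(bool)
    return ExpressionDataset(values.astype(float), annotations)


def write_expression(ds: ExpressionDataset, path) -> None:
    out = ds.values.copy()
    if ds.annotations is not None:
        ann = ds.annotations[[c for c in _ANNOT_COLS if c in ds.annotations]]
        out = pd.concat([ann, out], axis=1)
    out.index.name = "probe"
    out.to_csv(path, sep="\t")


def write_replicates(replicates: dict, directory) -> list[Path]:
    """Write the four replicate layers (signals s1/s2, bead counts b1/b2)
    as probes x samples TSVs under ``directory``."""
    directory = Path(directory)
    paths = []
    order = list(replicates)
    for layer in ("s1", "s2", "b1", "b2"):
        df = pd.DataFrame({sid: getattr(replicates[sid], layer) for sid in order})
        df.index.name = "probe"
        path = directory / f"replicates_{layer}.tsv"
        df.to_csv(path, sep="\t")
        paths.append(path)
    return paths


def read_replicates(directory) -> dict | None:
    """Load replicate layers written by :func:`write_replicates`; returns
    None when the files are absent."""
    from .preprocess import ReplicatePair

    directory = Path(directory)
    layers = {}
    for layer in ("s1", "s2", "b1", "b2"):
        path = directory / f"replicates_{layer}.tsv"
        if not path.exists():
            return None
        layers[layer] = pd.read_csv(path, sep="\t", index_col="probe")
    out = {}
    for sid in layers["s1"].columns:
        out[sid] = ReplicatePair(
            sid,
            layers["s1"][sid],
            layers["s2"][sid],
            layers["b1"][sid].astype(int),
            layers["b2"][sid].astype(int),
        )
    return out


# ---------------------------------------------------------------------------
# genotypes


def read_genotypes(path) -> GenotypeDataset:
    """Read genotypes from VCF (``.vcf``) or dosage TSV (anything else)."""
    path = Path(path)
    if path.suffix == ".vcf" or str(path).endswith(".vcf.gz"):
        return _read_vcf(path)
    _check_duplicate_header(path)
    df = pd.read_csv(path, sep="\t", dtype={"chromosome": str})
    for col in ("snp", "chromosome", "position"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing {col!r} column")
    df = df.set_index("snp")
    snps = df[["chromosome", "position"]].copy()
    dosages = df.drop(columns=["chromosome", "position"]).astype(float).T
    dosages.index.name = "sample"
    return GenotypeDataset(dosages, snps)


def write_genotypes(gd: GenotypeDataset, path) -> None:
    """Write dosage TSV (SNP rows) or VCF, by file extension."""
    path = Path(path)
    if path.suffix == ".vcf":
        _write_vcf(gd, path)
        return
    out = pd.concat([gd.snps[["chromosome", "position"]], gd.dosages.T], axis=1)
    out.index.name = "snp"
    out.to_csv(path, sep="\t")


def _write_vcf(gd: GenotypeDataset, path: Path) -> None:
    """Minimal VCF 4.2 with GT only; ALT is the minor allele, so the ALT
    allele count equals the stored dosage."""
    gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in pd.unique(gd.snps["chromosome"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(map(str, gd.samples))
            + "\n"
        )
        order = gd.snps.sort_values(["chromosome", "position"]).index
        for snp in order:
            row = gd.snps.loc[snp]
            calls = [
                gt_map.get(v, "./.")
                for v in gd.dosages[snp].tolist()
            ]
            fh.write(
                f"{row['chromosome']}\t{int(row['position'])}\t{snp}\tA\tG\t.\t"
                "PASS\t.\tGT\t" + "\t".join(calls) + "\n"
            )


def _read_vcf(path: Path) -> GenotypeDataset:
    """Parse a GT-only VCF into minor-allele dosages.

    Sites whose ALT allele turns out to be the major allele are flipped so
    the dosage always counts the minor allele; multi-allelic sites are
    skipped with a warning; malformed lines raise with their line number.
    """
    samples: list[str] = []
    ids, chroms, positions, rows = [], [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                fields = line.split("\t")
                if len(fields) < 10:
                    raise ValueError(f"{path}:{lineno}: VCF has no sample columns")
                samples = fields[9:]
                continue
            fields = line.split("\t")
            if len(fields) != 9 + len(samples):
                raise ValueError(
                    f"{path}:{lineno}: expected {9 + len(samples)} fields, "
                    f"got {len(fields)}"
                )
            chrom, pos, snp_id, _ref, alt = fields[:5]
            fmt = fields[8].split(":")
            if "GT" not in fmt:
                raise ValueError(f"{path}:{lineno}: no GT in FORMAT")
            if "," in alt:
                warnings.warn(f"{path}:{lineno}: multi-allelic site {snp_id} skipped")
                continue
            gt_idx = fmt.index("GT")
            alt_counts = []
            for call in fields[9:]:
                gt = call.split(":")[gt_idx].replace("|", "/")
                if gt in (".", "./."):
                    alt_counts.append(np.nan)
                    continue
                try:
                    alleles = [int(x) for x in gt.split("/")]
                except ValueError as exc:
                    raise ValueError(
                        f"{path}:{lineno}: malformed genotype {gt!r}"
                    ) from exc
                alt_counts.append(float(sum(a != 0 for a in alleles)))
            try:
                positions.append(int(pos))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: bad POS {pos!r}") from exc
            ids.append(snp_id)
            chroms.append(chrom)
            rows.append(alt_counts)

    dosages = np.asarray(rows, dtype=float).T if rows else np.empty((len(samples), 0))
    # recode so the dosage counts the minor allele
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        freq = np.nanmean(dosages, axis=0) / 2.0
    flip = freq > 0.5
    dosages[:, flip] = 2.0 - dosages[:, flip]
    snps = pd.DataFrame(
        {"chromosome": chroms, "position": positions},
        index=pd.Index(ids, name="snp"),
    )
    return GenotypeDataset(
        pd.DataFrame(dosages, index=pd.Index(samples, name="sample"),
                     columns=snps.index),
        snps,
    )


# ---------------------------------------------------------------------------
# traits and ground truth


def read_traits(path, traits: list[str] | None = None) -> TraitTable:
    _check_duplicate_header(Path(path))
    df = pd.read_csv(path, sep="\t", index_col="sample")
    known_cov = [c for c in ("age", "sex", "HTM", "CM", "alcohol") if c in df.columns]
    if traits is None:
        traits = [c for c in df.columns if c not in known_cov]
    return TraitTable(df, traits=list(traits), covariates=known_cov)


def write_traits(tt: TraitTable, path) -> None:
    out = tt.data.copy()
    out.index.name = "sample"
    out.to_csv(path, sep="\t")


def write_truth(truth, path) -> None:
    """Serialize a GroundTruth record to JSON (matrices as nested lists)."""
    payload = {
        "module_assignment": truth.module_assignment.to_dict(),
        "latent_factors": {
            "index": list(truth.latent_factors.index),
            "columns": list(truth.latent_factors.columns),
            "values": truth.latent_factors.to_numpy().tolist(),
        },
        "eqtl_map": {k: [v[0], v[1]] for k, v in truth.eqtl_map.items()},
        "anchor_map": {k: list(v) for k, v in truth.anchor_map.items()},
        "trait_loadings": None
        if truth.trait_loadings is None
        else {
            "index": list(truth.trait_loadings.index),
            "columns": list(truth.trait_loadings.columns),
            "values": truth.trait_loadings.to_numpy().tolist(),
        },
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def read_truth(path) -> dict:
    with open(path) as fh:
        payload = json.load(fh)
    payload["module_assignment"] = pd.Series(payload["module_assignment"])
    lf = payload["latent_factors"]
    payload["latent_factors"] = pd.DataFrame(
        lf["values"], index=lf["index"], columns=lf["columns"]
    )
    if payload.get("trait_loadings"):
        tl = payload["trait_loadings"]
        payload["trait_loadings"] = pd.DataFrame(
            tl["values"], index=tl["index"], columns=tl["columns"]
        )
    return payload
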