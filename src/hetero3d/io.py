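"""Readers and writers for the pipeline's on-disk text formats.

Matrices travel as a cooler-compatible triplet layout: a bin table TSV
(chrom, start, end; 0-based half-open, global bin ids implicit by row) plus
a COO TSV (bin1_id, bin2_id, count) holding the upper triangle
(bin1_id <= bin2_id). Tracks are bedGraph, genes BED6, TEs GFF3 with a
``superfamily=`` attribute, tables plain TSV, and the simulation manifest
YAML.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .genome import BinnedGenome
from .hicmatrix import ContactMatrix
from .tracks import SignalTrack

# %.17g round-trips IEEE doubles exactly (the on-disk dataset must reload
# to the in-memory objects bit-for-bit)
FLOAT_FMT = "%.17g"


# ---------------------------------------------------------------------------
# bins + COO matrices


def write_bins(genome: BinnedGenome, path) -> None:
    genome.bins.to_csv(path, sep="\t", index=False)


def read_bins(path) -> BinnedGenome:
    bins = pd.read_csv(path, sep="\t")
    sizes: dict[str, int] = {}
    widths = set()
    for chrom, grp in bins.groupby("chrom", sort=False):
        g = grp.sort_values("start")
        if (g["start"].to_numpy() != np.concatenate([[0], g["end"].to_numpy()[:-1]])).any():
            raise ValueError(f"bin table does not tile {chrom!r}")
        sizes[chrom] = int(g["end"].iloc[-1])
        widths.update((g["end"] - g["start"]).iloc[:-1].tolist())
        widths.add(int((g["end"] - g["start"]).iloc[0]))
    bin_size = max(int(w) for w in widths)
    return BinnedGenome.from_dict(sizes, bin_size)


def write_coo(matrix: ContactMatrix, path) -> None:
    """Upper-triangle COO TSV (bin1_id, bin2_id, count), global bin ids."""
    rows = []
    for chrom in matrix.genome.names:
        off = matrix.genome.chrom_offset(chrom)
        m = np.nan_to_num(matrix.data[chrom], nan=0.0)
        i, j = np.nonzero(np.triu(m))
        rows.append(pd.DataFrame({
            "bin1_id": i + off, "bin2_id": j + off, "count": m[i, j],
        }))
    table = pd.concat(rows, ignore_index=True)
    table.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_coo(path, genome: BinnedGenome) -> ContactMatrix:
    table = pd.read_csv(path, sep="\t", float_precision="round_trip")
    data = {c: np.zeros((genome.chrom_nbins(c),) * 2) for c in genome.names}
    bins = genome.bins
    chroms = bins["chrom"].to_numpy()
    offs = {c: genome.chrom_offset(c) for c in genome.names}
    for b1, b2, v in zip(table["bin1_id"], table["bin2_id"], table["count"]):
        c1, c2 = chroms[b1], chroms[b2]
        if c1 != c2:
            continue  # cis-only storage
        i, j = b1 - offs[c1], b2 - offs[c1]
        data[c1][i, j] = v
        data[c1][j, i] = v
    return ContactMatrix(genome=genome, data=data, stage="raw")


# ---------------------------------------------------------------------------
# tracks / intervals


def write_bedgraph(track: SignalTrack, path) -> None:
    bins = track.genome.bins
    out = bins.copy()
    out["value"] = track.values
    out.to_csv(path, sep="\t", index=False, header=False, float_format=FLOAT_FMT)


def read_bedgraph(path, genome: BinnedGenome, name: str) -> SignalTrack:
    table = pd.read_csv(path, sep="\t", header=None,
                        names=["chrom", "start", "end", "value"],
                        float_precision="round_trip")
    values = np.zeros(genome.n_bins)
    for chrom, grp in table.groupby("chrom", sort=False):
        sl = genome.chrom_slice(chrom)
        idx = grp["start"].to_numpy() // genome.bin_size
        values[sl.start + idx] = grp["value"].to_numpy()
    return SignalTrack(name, genome, values)


def write_bed6(intervals: pd.DataFrame, path) -> None:
    out = pd.DataFrame({
        "chrom": intervals["chrom"], "start": intervals["start"],
        "end": intervals["end"], "name": intervals["name"],
        "score": 0, "strand": intervals.get("strand", "+"),
    })
    out.to_csv(path, sep="\t", index=False, header=False)


def read_bed6(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", header=None,
                        names=["chrom", "start", "end", "name", "score", "strand"])
    return table.drop(columns=["score"])


def write_tes_gff3(tes: pd.DataFrame, path) -> None:
    """GFF3 (1-based inclusive) with ID=, superfamily= and location= attrs."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for _, te in tes.iterrows():
            attrs = f"ID={te['name']};superfamily={te['superfamily']}"
            if "location" in te and pd.notna(te["location"]):
                attrs += f";location={te['location']}"
            fh.write(
                f"{te['chrom']}\thetero3d_sim\ttransposable_element\t"
                f"{int(te['start']) + 1}\t{int(te['end'])}\t.\t+\t.\t{attrs}\n"
            )


def read_tes_gff3(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            attrs = dict(
                kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv
            )
            rows.append({
                "chrom": parts[0], "start": int(parts[3]) - 1, "end": int(parts[4]),
                "superfamily": attrs.get("superfamily", "unknown"),
                "location": attrs.get("location", np.nan),
                "name": attrs.get("ID", ""),
            })
    return pd.DataFrame(rows)


def write_bedpe(table: pd.DataFrame, genome: BinnedGenome, path) -> None:
    """Differential-interaction pairs as BEDPE (browser arc-track input)."""
    bs = genome.bin_size
    rows = []
    for k, r in table.reset_index(drop=True).iterrows():
        c = r["chrom"]
        rows.append({
            "chrom1": c, "start1": int(r["bin1"]) * bs, "end1": (int(r["bin1"]) + 1) * bs,
            "chrom2": c, "start2": int(r["bin2"]) * bs, "end2": (int(r["bin2"]) + 1) * bs,
            "name": f"diff_{k:06d}", "z": r["z"],
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, header=False,
                              float_format=FLOAT_FMT)


# ---------------------------------------------------------------------------
# whole-dataset round trip


def write_dataset(ds, outdir) -> None:
    """Write a :class:`~hetero3d.simgenome.SimulatedDataset` to a directory."""
    from dataclasses import asdict

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_bins(ds.genome, outdir / "bins.tsv")
    for genotype, matrix in ds.matrices.items():
        write_coo(matrix, outdir / f"matrix_{genotype}.coo.tsv")
    tracks_dir = outdir / "tracks"
    tracks_dir.mkdir(exist_ok=True)
    for genotype, marks in ds.tracks.items():
        for mark, track in marks.items():
            write_bedgraph(track, tracks_dir / f"{genotype}_{mark}.bedgraph")
    write_bed6(ds.genes, outdir / "genes.bed")
    write_tes_gff3(ds.tes, outdir / "tes.gff3")
    ds.de_table.to_csv(outdir / "de_table.tsv", sep="\t", index=False,
                       float_format=FLOAT_FMT)
    truth = ds.genome.bins.copy()
    truth["state_wt"] = ds.truth.state_wt
    truth["state_mut"] = ds.truth.state_mut
    truth["class_label"] = ds.truth.class_label
    truth["compartment_label"] = ds.truth.compartment_label
    truth.to_csv(outdir / "truth_bins.tsv", sep="\t")
    ds.truth.domains.to_csv(outdir / "truth_domains.tsv", sep="\t", index=False)
    ds.truth.anchor_pairs.to_csv(outdir / "truth_anchors.tsv", sep="\t", index=False)
    cfg = asdict(ds.config)
    cfg["anchor_d_range"] = list(cfg["anchor_d_range"])
    manifest = {
        "config": cfg,
        "coordinates": "0-based half-open (GFF3 file is 1-based inclusive)",
        "matrix_layout": "COO TSV upper triangle, global bin ids from bins.tsv",
    }
    with open(outdir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)


def read_dataset(outdir):
    """Load a dataset directory written by :func:`write_dataset`."""
    from .simgenome import SimulatedDataset, SimulationConfig, TruthSet

    outdir = Path(outdir)
    with open(outdir / "manifest.yaml") as fh:
        manifest = yaml.safe_load(fh)
    cfg_dict = manifest["config"]
    cfg_dict["anchor_d_range"] = tuple(cfg_dict["anchor_d_range"])
    cfg = SimulationConfig(**cfg_dict)
    genome = read_bins(outdir / "bins.tsv")
    matrices = {}
    for genotype in ("wt", "ddm1"):
        path = outdir / f"matrix_{genotype}.coo.tsv"
        if path.exists():
            matrices[genotype] = read_coo(path, genome)
    tracks: dict[str, dict[str, SignalTrack]] = {}
    for path in sorted((outdir / "tracks").glob("*.bedgraph")):
        genotype, mark = path.stem.split("_", 1)
        tracks.setdefault(genotype, {})[mark] = read_bedgraph(path, genome, mark)
    genes = read_bed6(outdir / "genes.bed")
    tes = read_tes_gff3(outdir / "tes.gff3")
    de = pd.read_csv(outdir / "de_table.tsv", sep="\t",
                     float_precision="round_trip")
    tb = pd.read_csv(outdir / "truth_bins.tsv", sep="\t", index_col=0)
    truth = TruthSet(
        genome=genome,
        state_wt=tb["state_wt"].to_numpy(dtype=object),
        state_mut=tb["state_mut"].to_numpy(dtype=object),
        domains=pd.read_csv(outdir / "truth_domains.tsv", sep="\t"),
        anchor_pairs=pd.read_csv(outdir / "truth_anchors.tsv", sep="\t"),
        class_label=tb["class_label"].to_numpy(dtype=object),
        compartment_label=tb["compartment_label"].to_numpy(dtype=object),
    )
    return SimulatedDataset(cfg, genome, truth, matrices, tracks, genes, tes, de)
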