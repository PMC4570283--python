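"""Reading and writing genotype panels (VCF 4.2 and PLINK text .ped/.map).

Derived-allele orientation follows the ``AA`` (ancestral allele) INFO field
when present; otherwise REF is treated as ancestral and a warning is logged.
Multiallelic and indel records are skipped and counted.  A structured-text
sidecar (:func:`write_truth` / :func:`read_truth`) preserves the generating
tree, seeds and spiked loci of synthetic datasets.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .datasets import MISSING, VARIANT_COLUMNS, GenotypeDataset
from .simulate import SyntheticTruth
from .trees import PopulationTree

logger = logging.getLogger(__name__)

_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def read_genotypes(path: str | Path, format: str | None = None) -> GenotypeDataset:
    """Read a genotype panel; ``format`` is ``'vcf'`` or ``'plink_text'``.

    With ``format=None`` the format is inferred from the file suffix
    (``.vcf``/``.vcf.gz`` vs ``.ped``).  Population labels are taken from a
    ``<stem>.pops`` two-column sidecar for VCF (sample, population) and from
    the family id column for PLINK; samples without a label fall back to
    population ``"unknown"``.
    """
    path = Path(path)
    if format is None:
        format = "vcf" if ".vcf" in path.suffixes or path.suffix == ".vcf" else "plink_text"
    if format == "vcf":
        return _read_vcf(path)
    if format == "plink_text":
        return _read_plink_text(path)
    raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------- VCF
def write_vcf(dataset: GenotypeDataset, path: str | Path) -> None:
    """Write a minimal VCF 4.2 with GT genotypes, INFO/AA and INFO/CM.

    REF is the ancestral allele and ALT the derived allele, so dosages map
    directly onto 0/0, 0/1, 1/1.  A ``<stem>.pops`` sidecar records the
    population labels.
    """
    path = Path(path)
    v = dataset.variants
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">\n')
        fh.write('##INFO=<ID=CM,Number=1,Type=Float,Description="Genetic position in cM">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in v["chrom"].unique():
            length = int(v.loc[v["chrom"] == chrom, "pos_bp"].max()) + 1
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(dataset.samples["sample_id"])
            + "\n"
        )
        for j in range(dataset.n_variants):
            row = v.iloc[j]
            gts = "\t".join(_GT_STRINGS[int(d)] for d in dataset.dosages[:, j])
            fh.write(
                f"{row.chrom}\t{row.pos_bp}\t{row.id}\t{row.ancestral}\t{row.derived}"
                f"\t.\t.\tAA={row.ancestral};CM={row.pos_cM:.6f}\tGT\t{gts}\n"
            )
    _write_pops_sidecar(dataset, path)


def _write_pops_sidecar(dataset: GenotypeDataset, path: Path) -> None:
    dataset.samples.to_csv(path.with_suffix(".pops"), sep="\t", index=False, header=False)


def _read_pops_sidecar(path: Path, sample_ids: list[str]) -> pd.DataFrame:
    pops_path = path.with_suffix(".pops")
    if pops_path.exists():
        tab = pd.read_csv(pops_path, sep="\t", names=["sample_id", "population"])
        mapping = dict(zip(tab["sample_id"], tab["population"]))
    else:
        mapping = {}
    return pd.DataFrame(
        {"sample_id": sample_ids, "population": [mapping.get(s, "unknown") for s in sample_ids]}
    )


def _read_vcf(path: Path) -> GenotypeDataset:
    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    if not samples:
        raise ValueError("VCF has no samples / GT field")
    rows, columns, skipped, no_aa = [], [], 0, 0
    for rec in vcf:
        if len(rec.ALT) != 1 or len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            skipped += 1
            continue
        gt = np.asarray(rec.gt_types, dtype=np.int8)  # 0/1/2 alt copies, 3 unknown
        if gt.shape[0] != len(samples):
            raise ValueError(f"inconsistent sample count at {rec.CHROM}:{rec.POS}")
        dosage = np.where(gt == 3, MISSING, gt).astype(np.int8)
        aa = rec.INFO.get("AA")
        ancestral, derived = rec.REF, rec.ALT[0]
        if aa is None:
            no_aa += 1
        elif aa.upper() == rec.ALT[0].upper():
            # ALT is ancestral: complement dosages so they count derived copies
            dosage = np.where(dosage == MISSING, MISSING, 2 - dosage).astype(np.int8)
            ancestral, derived = rec.ALT[0], rec.REF
        elif aa.upper() != rec.REF.upper():
            skipped += 1  # AA matches neither allele
            continue
        cm = rec.INFO.get("CM")
        rows.append(dosage)
        columns.append(
            (
                rec.ID or f"{rec.CHROM}:{rec.POS}",
                str(rec.CHROM),
                rec.POS,
                float(cm) if cm is not None else rec.POS / 1e6,
                ancestral,
                derived,
            )
        )
    if skipped:
        logger.info("skipped %d multiallelic/indel/unorientable records", skipped)
    if no_aa:
        warnings.warn(
            f"{no_aa} records lack INFO/AA; REF treated as ancestral", stacklevel=3
        )
    variants = pd.DataFrame(columns, columns=VARIANT_COLUMNS)
    dosages = np.column_stack(rows) if rows else np.zeros((len(samples), 0), dtype=np.int8)
    return GenotypeDataset(dosages, variants, _read_pops_sidecar(path, samples))


# ---------------------------------------------------------------------- PLINK text
def write_plink_text(dataset: GenotypeDataset, prefix: str | Path) -> None:
    """Write PLINK text ``.ped``/``.map`` (cM in .map column 3).

    The family id column carries the population label, which
    :func:`read_genotypes` maps back onto the sample table.  Because the
    .ped format has no ancestral-allele slot, an ``.anc`` sidecar
    (variant id, ancestral, derived) preserves orientation for exact
    round-trips.
    """
    prefix = Path(prefix)
    v = dataset.variants
    pd.DataFrame(
        {"chrom": v["chrom"], "id": v["id"], "cM": v["pos_cM"], "bp": v["pos_bp"]}
    ).to_csv(prefix.with_suffix(".map"), sep="\t", index=False, header=False)
    v[["id", "ancestral", "derived"]].to_csv(
        prefix.with_suffix(".anc"), sep="\t", index=False, header=False
    )

    anc = v["ancestral"].to_numpy()
    der = v["derived"].to_numpy()
    with open(prefix.with_suffix(".ped"), "w") as fh:
        for i, row in dataset.samples.iterrows():
            alleles = []
            for j, d in enumerate(dataset.dosages[i]):
                if d == MISSING:
                    alleles.append("0 0")
                else:
                    alleles.append(
                        f"{der[j] if d >= 1 else anc[j]} {der[j] if d == 2 else anc[j]}"
                    )
            fh.write(
                f"{row.population} {row.sample_id} 0 0 0 -9 " + " ".join(alleles) + "\n"
            )


def _read_plink_text(path: Path) -> GenotypeDataset:
    prefix = Path(str(path).removesuffix(".ped"))
    vmap = pd.read_csv(
        prefix.with_suffix(".map"),
        sep=r"\s+",
        names=["chrom", "id", "pos_cM", "pos_bp"],
        dtype={"chrom": str},
    )
    n_var = len(vmap)
    sample_rows, geno_rows = [], []
    with open(prefix.with_suffix(".ped")) as fh:
        for line in fh:
            parts = line.split()
            if len(parts) != 6 + 2 * n_var:
                raise ValueError("inconsistent column count in .ped")
            sample_rows.append((parts[1], parts[0]))
            geno_rows.append(parts[6:])
    alleles = np.array(geno_rows, dtype="U8").reshape(len(geno_rows), n_var, 2)

    # Orientation: prefer the .anc sidecar written alongside; without it the
    # first non-missing allele seen is provisional-ancestral (the .ped format
    # itself carries no ancestral annotation).
    anc_path = prefix.with_suffix(".anc")
    known: dict[str, tuple[str, str]] = {}
    if anc_path.exists():
        tab = pd.read_csv(anc_path, sep="\t", names=["id", "ancestral", "derived"])
        known = {r.id: (r.ancestral, r.derived) for r in tab.itertuples()}
    else:
        warnings.warn(
            "no .anc sidecar: PLINK text carries no ancestral-allele annotation; "
            "orientation inferred from allele order",
            stacklevel=3,
        )
    dosages = np.full((len(geno_rows), n_var), MISSING, dtype=np.int8)
    anc_list, der_list = [], []
    for j in range(n_var):
        col = alleles[:, j, :]
        obs = col[col != "0"]
        uniq = pd.unique(obs)
        if uniq.size > 2:
            raise ValueError(f"variant {vmap['id'][j]} has >2 alleles")
        if vmap["id"][j] in known:
            anc, der = known[vmap["id"][j]]
        else:
            anc = uniq[0] if uniq.size else "A"
            der = uniq[1] if uniq.size > 1 else ("G" if anc != "G" else "T")
        anc_list.append(anc)
        der_list.append(der)
        missing = (col == "0").any(axis=1)
        dosages[:, j] = np.where(missing, MISSING, (col == der).sum(axis=1))
    samples = pd.DataFrame(sample_rows, columns=["sample_id", "population"])
    variants = pd.DataFrame(
        {
            "id": vmap["id"],
            "chrom": vmap["chrom"],
            "pos_bp": vmap["pos_bp"],
            "pos_cM": vmap["pos_cM"],
            "ancestral": anc_list,
            "derived": der_list,
        },
        columns=VARIANT_COLUMNS,
    )
    return GenotypeDataset(dosages, variants, samples)


# ---------------------------------------------------------------------- truth sidecar
def write_truth(truth: SyntheticTruth, path: str | Path) -> None:
    """Serialise a SyntheticTruth (tree, seeds, spiked loci) as JSON."""
    tree = truth.tree
    payload = {
        "seed": truth.seed,
        "tree": {
            "root": tree.root,
            "root_spectrum": list(tree.root_spectrum),
            "branches": {
                c: {"parent": b.parent, "length": b.length, "ne": b.ne}
                for c, b in tree.branches.items()
            },
        },
        "expected_fst": {f"{a}|{b}": v for (a, b), v in truth.expected_fst.items()},
        "spiked_loci": truth.spiked_loci,
        "monomorphic_loci": np.flatnonzero(truth.monomorphic).tolist(),
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def read_truth(path: str | Path) -> dict:
    """Load a truth sidecar; the tree is rebuilt as a PopulationTree."""
    payload = json.loads(Path(path).read_text())
    t = payload["tree"]
    payload["tree"] = PopulationTree.from_dict(
        t["root"],
        {c: (b["parent"], b["length"], b["ne"]) for c, b in t["branches"].items()},
        root_spectrum=tuple(t["root_spectrum"]),
    )
    payload["expected_fst"] = {
        tuple(k.split("|")): v for k, v in payload["expected_fst"].items()
    }
    return payload
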