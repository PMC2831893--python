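"""Stage orchestration with provenance: each ``run_*`` function executes one
pipeline stage, writes its outputs (machine-readable JSON plus TSV tables)
into an output directory, and returns the report dictionary.

Reports are reproducible bit-for-bit from the same configuration and seed:
provenance blocks record the package version, the seed and a hash of the
configuration, never wall-clock time.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .ancestral import annotate_cpg, classify_substitutions, fitch_reconstruct
from .codonmodel import CodonModelParams
from .model import CladeDnDsModel, likelihood_ratio_test
from .retrolocus import digest_sequence, find_tsd, in_silico_pcr, scan_en_sites
from .seqio import (
    CodonAlignment,
    filter_codon_columns,
    load_alignment,
    load_sequences,
    write_alignment,
)
from .simulate import SimConfig, simulate_alignment, simulate_insertion_locus
from .trees import load_tree


def _provenance(config: dict) -> dict:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return {
        "version": __version__,
        "config": config,
        "config_sha256": hashlib.sha256(blob).hexdigest(),
    }


def _write_report(outdir: Path, name: str, report: dict) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / f"{name}.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")


class StageError(RuntimeError):
    """An error in a named pipeline stage."""

    def __init__(self, stage: str, original: Exception) -> None:
        super().__init__(f"[{stage}] {original}")
        self.stage = stage


def run_fit(
    alignment_path,
    tree_path,
    outdir,
    *,
    seed: int = 0,
    multistart: int = 3,
    frequencies: str = "f3x4",
    stop_policy: str = "error",
) -> dict:
    """Filter the alignment, fit M0 and the clades model, and run the LRT.

    Writes ``fit.json`` plus an omega/SE table and the LRT table as TSV.
    """
    outdir = Path(outdir)
    config = {
        "stage": "fit",
        "alignment": str(alignment_path),
        "tree": str(tree_path),
        "seed": seed,
        "multistart": multistart,
        "frequencies": frequencies,
        "stop_policy": stop_policy,
    }
    try:
        aln = load_alignment(alignment_path)
        tree = load_tree(tree_path)
        filtered = filter_codon_columns(aln, stop_policy=stop_policy)
    except Exception as exc:  # noqa: BLE001 - stage tagging
        raise StageError("input", exc) from exc
    try:
        m0 = CladeDnDsModel(
            filtered, tree, one_ratio=True, frequencies=frequencies, prefiltered=True
        ).fit(multistart=multistart, seed=seed)
        clades = CladeDnDsModel(
            filtered, tree, frequencies=frequencies, prefiltered=True
        ).fit(multistart=multistart, seed=seed)
        lrt = likelihood_ratio_test(m0, clades)
    except Exception as exc:  # noqa: BLE001
        raise StageError("fit", exc) from exc
    report = {
        "provenance": _provenance(config),
        "n_columns_input": aln.n_sites,
        "n_columns_filtered": filtered.n_sites,
        "n_patterns": clades.n_patterns,
        "m0": m0.to_dict(),
        "clades": clades.to_dict(),
        "lrt": {"delta": lrt.delta, "df": lrt.df, "p": lrt.p},
    }
    _write_report(outdir, "fit", report)
    rows = [
        {"model": "M0", "parameter": "kappa", "estimate": m0.kappa, "se": m0.se.get("kappa")},
        {"model": "M0", "parameter": "omega0", "estimate": m0.omega[0], "se": m0.se.get("omega0")},
        {"model": "clades", "parameter": "kappa", "estimate": clades.kappa, "se": clades.se.get("kappa")},
    ]
    for k in sorted(clades.omega):
        rows.append(
            {
                "model": "clades",
                "parameter": f"omega{k}",
                "estimate": clades.omega[k],
                "se": clades.se.get(f"omega{k}"),
            }
        )
    pd.DataFrame(rows).to_csv(outdir / "fit_params.tsv", sep="\t", index=False)
    pd.DataFrame(
        [{"lnL_M0": m0.lnl, "lnL_clades": clades.lnl, "delta": lrt.delta, "df": lrt.df, "p": lrt.p}]
    ).to_csv(outdir / "lrt.tsv", sep="\t", index=False)
    return report


def run_simulate(
    tree_path,
    outdir,
    *,
    n_codons: int = 250,
    kappa: float = 2.0,
    omega: tuple[float, ...] = (0.05, 0.30),
    seed: int = 0,
    cpg_bias: float = 1.0,
) -> dict:
    """Simulate an alignment under the clades model along a labelled tree."""
    outdir = Path(outdir)
    config = {
        "stage": "simulate",
        "tree": str(tree_path),
        "n_codons": n_codons,
        "kappa": kappa,
        "omega": list(omega),
        "seed": seed,
        "cpg_bias": cpg_bias,
    }
    try:
        tree = load_tree(tree_path)
        needed = tree.n_partitions()
        if len(omega) < needed:
            raise ValueError(
                f"tree has {needed} partitions but only {len(omega)} omegas given"
            )
        params = CodonModelParams(
            kappa=kappa,
            omega_by_partition={k: omega[k] for k in range(needed)},
            pi=np.full(61, 1 / 61),
        )
        cfg = SimConfig(
            tree=tree, params=params, n_codons=n_codons, seed=seed, cpg_bias=cpg_bias
        )
        aln, truth = simulate_alignment(cfg)
    except Exception as exc:  # noqa: BLE001
        raise StageError("simulate", exc) from exc
    outdir.mkdir(parents=True, exist_ok=True)
    write_alignment(aln, outdir / "alignment.fasta")
    with open(outdir / "tree.nwk", "w") as fh:
        fh.write(truth.tree.to_newick() + "\n")
    events = pd.DataFrame(
        [
            {
                "branch": e.branch,
                "time": e.time,
                "site": e.site + 1,
                "codon_pos": e.codon_pos + 1,
                "change": f"{e.from_nt}->{e.to_nt}",
                "class": "synonymous" if e.synonymous else "nonsynonymous",
                "cpg_context": e.cpg_context,
            }
            for e in truth.events
        ]
    )
    with open(outdir / "events.tsv", "w") as fh:
        fh.write(f"# seed={seed} kappa={kappa} omega={list(omega)} cpg_bias={cpg_bias}\n")
        events.to_csv(fh, sep="\t", index=False)
    report = {
        "provenance": _provenance(config),
        "n_events": len(truth.events),
        "branch_counts": truth.branch_counts(),
        "true_omega": truth.true_omega,
    }
    _write_report(outdir, "simulate", report)
    return report


def run_ancestors(
    alignment_path,
    tree_path,
    outdir,
    *,
    sites: list[int] | None = None,
    outgroup: str | None = None,
) -> dict:
    """Maximum-parsimony ancestral codons with substitution annotation."""
    outdir = Path(outdir)
    config = {
        "stage": "ancestors",
        "alignment": str(alignment_path),
        "tree": str(tree_path),
        "sites": sites,
        "outgroup": outgroup,
    }
    try:
        aln = load_alignment(alignment_path)
        tree = load_tree(tree_path)
        recon = fitch_reconstruct(tree, aln, sites, outgroup=outgroup)
        classify_substitutions(recon)
        if sites is None:
            annotate_cpg(recon)
    except Exception as exc:  # noqa: BLE001
        raise StageError("ancestors", exc) from exc
    outdir.mkdir(parents=True, exist_ok=True)
    recon.to_table().to_csv(outdir / "events.tsv", sep="\t", index=False)
    report = {
        "provenance": _provenance(config),
        "n_changes": recon.n_changes,
        "events": [
            {
                "branch": e.branch,
                "site": e.site,
                "notation": e.notation,
                "class": "synonymous" if e.synonymous else "nonsynonymous",
                "cpg": e.cpg_flag,
            }
            for e in recon.events
        ],
    }
    _write_report(outdir, "ancestors", report)
    return report


def run_locus(
    outdir,
    *,
    flank_len: int = 400,
    tsd_len: int = 12,
    insert_len: int = 600,
    seed: int = 0,
    max_mismatch: int = 0,
) -> dict:
    """Simulate a retrocopy insertion locus and re-detect TSD and EN sites."""
    outdir = Path(outdir)
    config = {
        "stage": "locus",
        "flank_len": flank_len,
        "tsd_len": tsd_len,
        "insert_len": insert_len,
        "seed": seed,
        "max_mismatch": max_mismatch,
    }
    try:
        rng = np.random.default_rng(seed + 1)
        insert = "".join(rng.choice(list("ACGT"), size=insert_len))
        locus = simulate_insertion_locus(flank_len, tsd_len, insert, seed)
        call = find_tsd(locus.sequence, locus.insert_interval, max_mismatch=max_mismatch)
        en_hits = scan_en_sites(locus.sequence)
    except Exception as exc:  # noqa: BLE001
        raise StageError("locus", exc) from exc
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "locus.fasta", "w") as fh:
        fh.write(f">synthetic_locus seed={seed}\n{locus.sequence}\n")
    # genomic intervals as BED (0-based half-open)
    with open(outdir / "locus.bed", "w") as fh:
        name = "synthetic_locus"
        fh.write(f"{name}\t{locus.insert_interval[0]}\t{locus.insert_interval[1]}\tinsert\n")
        if locus.tsd:
            fh.write(f"{name}\t{locus.tsd5_interval[0]}\t{locus.tsd5_interval[1]}\ttsd_5prime\n")
            fh.write(f"{name}\t{locus.tsd3_interval[0]}\t{locus.tsd3_interval[1]}\ttsd_3prime\n")
        fh.write(f"{name}\t{locus.en_site - 4}\t{locus.en_site + 1}\ten_motif\n")
    report = {
        "provenance": _provenance(config),
        "truth": {
            "insert_interval": list(locus.insert_interval),
            "tsd": locus.tsd,
            "en_site": locus.en_site,
        },
        "tsd_call": None
        if call is None
        else {
            "repeat": call.repeat,
            "five_prime": list(call.five_prime),
            "three_prime": list(call.three_prime),
            "mismatches": call.mismatches,
            "en_site": call.en_site,
        },
        "en_sites": [
            {"position": h.position, "strand": h.strand, "extended": h.extended}
            for h in en_hits
        ],
    }
    _write_report(outdir, "locus", report)
    return report


def run_pcr_digest(
    template_path,
    fwd: str,
    rev: str,
    outdir,
    *,
    enzyme: str = "NlaIV",
    max_mismatch: int = 0,
) -> dict:
    """In-silico PCR followed by a restriction digest of the amplicon."""
    outdir = Path(outdir)
    config = {
        "stage": "pcr-digest",
        "template": str(template_path),
        "fwd": fwd,
        "rev": rev,
        "enzyme": enzyme,
        "max_mismatch": max_mismatch,
    }
    try:
        records = load_sequences(template_path)
        results = []
        for rec in records:
            try:
                amp = in_silico_pcr(rec, fwd, rev, max_mismatch=max_mismatch)
            except ValueError as exc:
                results.append({"template": rec.id, "error": str(exc)})
                continue
            digest = digest_sequence(amp.sequence, enzyme)
            results.append(
                {
                    "template": rec.id,
                    "amplicon_start": amp.start,
                    "amplicon_end": amp.end,
                    "amplicon_length": amp.length,
                    "enzyme": digest.enzyme,
                    "cut_positions": digest.cut_positions,
                    "fragment_lengths": digest.fragment_lengths,
                }
            )
    except Exception as exc:  # noqa: BLE001
        raise StageError("pcr-digest", exc) from exc
    report = {"provenance": _provenance(config), "results": results}
    _write_report(outdir, "pcr_digest", report)
    pd.DataFrame(results).to_csv(Path(outdir) / "pcr_digest.tsv", sep="\t", index=False)
    return report
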