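"""Length distributions, Venn partition, composition table, CLI and
pipeline determinism."""

import itertools
import json

import pytest
from click.testing import CliRunner

from soymir.cli import main as cli_main
from soymir.preprocess import CleanReadSet
from soymir.report import length_distribution, venn


def make_set(lib, seqs_counts):
    return CleanReadSet(lib, dict(seqs_counts))


class TestLengthDistribution:
    def test_two_length_classes(self):
        clean = make_set("l", {"A" * 21: 5, "C" * 24: 10})
        dist = length_distribution(clean)
        assert dist.loc[21, "unique"] == 1 and dist.loc[21, "total"] == 5
        assert dist.loc[24, "unique"] == 1 and dist.loc[24, "total"] == 10
        assert dist["total"].sum() == clean.total
        assert dist["unique"].sum() == clean.unique

    def test_empty_set(self):
        dist = length_distribution(make_set("l", {}))
        assert dist["total"].sum() == 0 and dist["unique"].sum() == 0

    def test_totals_conserved_on_simulated_library(self, small_pipeline):
        for lib, clean in small_pipeline.clean_sets.items():
            dist = length_distribution(clean)
            assert dist["total"].sum() == clean.total
            assert dist["unique"].sum() == clean.unique


def brute_force_venn(sets):
    """Subset partition by explicit enumeration over every sequence."""
    libs = list(sets)
    union = set().union(*(set(s.counts) for s in sets.values()))
    partition = {}
    for seq in union:
        members = tuple(lib for lib in libs if seq in sets[lib].counts)
        partition.setdefault(members, []).append(seq)
    return partition


class TestVenn:
    def test_identical_sets_fully_shared(self):
        counts = {"A" * 20: 5, "C" * 21: 2}
        sets = {lib: make_set(lib, counts) for lib in "WXYZ"}
        summary = venn(sets)
        assert summary.shared_unique_pct == 100.0
        assert summary.shared_total_pct == 100.0

    def test_disjoint_sets_share_nothing(self):
        sets = {
            "W": make_set("W", {"A" * 20: 5}),
            "X": make_set("X", {"C" * 20: 5}),
            "Y": make_set("Y", {"G" * 20: 5}),
        }
        summary = venn(sets)
        assert summary.shared_unique_pct == 0.0
        assert summary.shared_total_pct == 0.0

    def test_three_library_toy_matches_brute_force(self):
        seqs = ["".join(c) for c in itertools.product("ACGT", repeat=2)]
        seqs = [s * 10 for s in seqs]  # 16 distinct 20-mers
        sets = {
            "W": make_set("W", {s: i + 1 for i, s in enumerate(seqs[:10])}),
            "X": make_set("X", {s: 2 for s in seqs[5:14]}),
            "Y": make_set("Y", {s: 3 for s in seqs[8:16]}),
        }
        summary = venn(sets)
        brute = brute_force_venn(sets)
        for row in summary.membership.itertuples():
            members = tuple(row.libraries.split(","))
            expected = brute.get(members, [])
            assert row.unique == len(expected), members
            expected_total = sum(
                sets[lib].counts.get(s, 0) for s in expected for lib in sets
            )
            assert row.total == expected_total, members
        # partition property: subset unique counts sum to the union size
        assert summary.membership["unique"].sum() == len(
            set().union(*(set(s.counts) for s in sets.values()))
        )

    def test_rejects_single_library(self):
        with pytest.raises(ValueError):
            venn({"W": make_set("W", {"A" * 20: 1})})


class TestCompositionSummary:
    def test_partition_identities_hold(self, small_pipeline):
        df = small_pipeline.summary
        truth = small_pipeline.dataset.truth
        for lib in truth.config.library_ids:
            t = f"{lib}_total"
            assert (
                df.loc["clean_reads_15_30nt", t]
                == df.loc["matching_genome", t]
                + df.loc["not_matching_genome", t]
            )
            assert (
                df.loc["matching_genome", t]
                == df.loc["intergenic", t] + df.loc["gene_transcripts", t]
            )
            assert (
                df.loc["gene_transcripts", t]
                == df.loc["exon", t] + df.loc["intron", t]
            )
            assert (
                df.loc["unknown_reads", t]
                == df.loc["clean_reads_15_30nt", t]
                - df.loc["mature_mirnas", t]
                - df.loc["matching_ncrna", t]
            )
            ncrna_cls = sum(
                df.loc[f"ncrna_{c}", t] for c in ("rRNA", "tRNA", "snoRNA", "other")
            )
            assert df.loc["matching_ncrna", t] == ncrna_cls

    def test_rrna_class_dominates_ncrna_removal(self, small_pipeline):
        df = small_pipeline.summary
        lib = small_pipeline.dataset.truth.config.library_ids[0]
        assert (
            df.loc["ncrna_rRNA", f"{lib}_total"]
            > 0.9 * df.loc["matching_ncrna", f"{lib}_total"]
        )


class TestPipelineOutputs:
    def test_same_seed_byte_identical_tables(self, tmp_path):
        from soymir.pipeline import run_pipeline
        from soymir.simulate import SimConfig

        digests = []
        for run in ("a", "b"):
            out = tmp_path / run
            cfg = SimConfig(seed=7, per_library_depth=3000)
            run_pipeline(cfg, str(out), write_outputs=True, quiet=True)
            digests.append(
                {
                    p.name: p.read_bytes()
                    for p in sorted(out.iterdir())
                    if p.suffix in {".tsv", ".fa", ".fastq", ".gff3"}
                }
            )
        assert digests[0].keys() == digests[1].keys()
        for name in digests[0]:
            assert digests[0][name] == digests[1][name], name

    def test_expected_artifacts_written(self, small_pipeline):
        import os

        expected = [
            "genome.fa",
            "annotation.gff3",
            "mature.fa",
            "precursors.fa",
            "ncrna.fa",
            "truth_counts.tsv",
            "mature_counts.tsv",
            "composition_summary.tsv",
            "venn_membership.tsv",
            "novel_candidates.tsv",
            "run_manifest.json",
        ]
        for name in expected:
            assert os.path.exists(os.path.join(small_pipeline.outdir, name)), name
        with open(os.path.join(small_pipeline.outdir, "run_manifest.json")) as fh:
            manifest = json.load(fh)
        assert manifest["seed"] == small_pipeline.dataset.truth.config.seed


class TestCli:
    def test_simulate_then_preprocess_roundtrip(self, tmp_path):
        runner = CliRunner()
        outdir = tmp_path / "sim"
        result = runner.invoke(
            cli_main,
            ["simulate", "--seed", "3", "--outdir", str(outdir)],
            catch_exceptions=False,
        )
        assert result.exit_code == 0
        # depth defaults are too big for a CLI smoke test; write a config
        cfg_path = tmp_path / "cfg.yaml"
        cfg_path.write_text("seed: 3\nper_library_depth: 1500\n")
        outdir2 = tmp_path / "sim2"
        result = runner.invoke(
            cli_main,
            ["simulate", "--config", str(cfg_path), "--outdir", str(outdir2)],
            catch_exceptions=False,
        )
        assert result.exit_code == 0
        clean_out = tmp_path / "clean.tsv"
        result = runner.invoke(
            cli_main,
            [
                "preprocess",
                "--fastq",
                str(outdir2 / "MON.fastq"),
                "--adapter",
                "TGGAATTCTCGGGTGCCAAGG",
                "--library-id",
                "MON",
                "--out",
                str(clean_out),
            ],
            catch_exceptions=False,
        )
        assert result.exit_code == 0
        assert "raw=1500" in result.output

    def test_run_all_completes_end_to_end(self, tmp_path):
        runner = CliRunner()
        cfg_path = tmp_path / "cfg.yaml"
        cfg_path.write_text(
            "seed: 4\nper_library_depth: 2000\ncorruption_fraction: 0.0\n"
        )
        outdir = tmp_path / "runall"
        result = runner.invoke(
            cli_main,
            ["run-all", "--config", str(cfg_path), "--outdir", str(outdir)],
            catch_exceptions=False,
        )
        assert result.exit_code == 0
        payload = json.loads(result.output[result.output.index("{") :])
        assert payload["clean_totals"]["MON"] == 2000

    def test_missing_input_file_reported(self, tmp_path):
        runner = CliRunner()
        result = runner.invoke(
            cli_main,
            ["preprocess", "--fastq", str(tmp_path / "nope.fastq"),
             "--adapter", "TGGAATTCTCGGGTGCCAAGG", "--out", "x.tsv"],
        )
        assert result.exit_code != 0
        assert "nope.fastq" in result.output
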