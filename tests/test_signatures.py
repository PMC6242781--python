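"""Diagnostic-site calling and signature-window extraction."""

import numpy as np
import pytest

from conftest import naive_diagnostic_columns
from signet.align import Alignment
from signet.seqio import ReferencePanel, Role, SeqRecord
from signet.signatures import (
    DiscoveryError,
    NucleotideSignature,
    SignatureConstraints,
    extract_signature,
    find_diagnostic_sites,
    verify_uniqueness,
)
from signet.synthetic import PanelSpec, simulate_panel

CY_SIGNATURE = "CAATTATTTGAGGTGCATTGTAAGAAGCGT"  # published 30-mer


def _panel_from_rows(rows):
    """rows: [(id, species, seq)] with equal lengths, roles auto-assigned."""
    species = []
    for _, sp, _ in rows:
        if sp not in species:
            species.append(sp)
    roles = {sp: (Role.OFFICIAL if i == 0 else Role.ADULTERANT)
             for i, sp in enumerate(species)}
    recs = [SeqRecord(rid, seq, species=sp, role=roles[sp])
            for rid, sp, seq in rows]
    panel = ReferencePanel(records=recs, species_roles=roles)
    aln = Alignment.from_equal_length(recs)
    return panel, aln


class TestFindDiagnosticSites:
    def test_no_variation_no_sites(self):
        seq = "ACGTACGTACGTACGTACGT"
        panel, aln = _panel_from_rows(
            [("a", "X", seq), ("b", "X", seq), ("c", "Y", seq), ("d", "Y", seq)]
        )
        assert find_diagnostic_sites(aln, panel, "X") == []

    def test_planted_columns_recovered_exactly(self, planted_panel, planted_alignment):
        sites = find_diagnostic_sites(planted_alignment, planted_panel, "S2")
        cols = {s.column for s in sites}
        assert {90, 110} <= cols

    def test_equals_naive_column_scan_on_synthetic_panels(self):
        """Oracle equivalence over seeded panels with intraspecies noise."""
        for seed in (1, 2, 3, 4, 5):
            spec = PanelSpec(
                seed=seed,
                n_species=4,
                n_seq_per_species=4,
                seq_length=150,
                interspecies_divergence=0.06,
                intraspecies_divergence=0.01,
                planted_sites={"S3": [(40, "C"), (77, "T")]},
            )
            panel = simulate_panel(spec)
            aln = Alignment.from_equal_length(panel.records)
            rows = [(r.species, r.seq) for r in panel.records]
            for target in ("S1", "S2", "S3", "S4"):
                got = [s.column for s in find_diagnostic_sites(aln, panel, target)]
                want = naive_diagnostic_columns(rows, target)
                assert got == want, (seed, target)

    def test_fixedness_threshold_boundary(self):
        base = "ACGTACGTACGTACGTACGTACGTACGTAC"
        tgt_rows = [("t%d" % i, "T", base) for i in range(5)]
        # plant allele T at column 10 (background base there is G) in 4 of 5
        planted = base[:10] + "T" + base[11:]
        rows = [(rid, sp, planted) for rid, sp, _ in tgt_rows[:4]]
        rows.append(tgt_rows[4])  # carries background base at col 10
        rows.append(("b1", "B", base))
        panel, aln = _panel_from_rows(rows)
        strict = find_diagnostic_sites(aln, panel, "T",
                                       SignatureConstraints(fixedness=1.0))
        assert 10 not in {s.column for s in strict}
        loose = find_diagnostic_sites(aln, panel, "T",
                                      SignatureConstraints(fixedness=0.8))
        assert 10 in {s.column for s in loose}

    def test_ambiguity_in_background_disqualifies(self):
        base = "ACGTACGTACGTACGTACGTACGTACGTAC"
        tgt = base[:5] + "A" + base[6:]
        bkg = base[:5] + "R" + base[6:]  # R = A/G contains the target allele
        panel, aln = _panel_from_rows([("t", "T", tgt), ("b", "B", bkg)])
        assert 5 not in {s.column for s in find_diagnostic_sites(aln, panel, "T")}

    def test_missing_target_raises(self, planted_panel, planted_alignment):
        with pytest.raises(LookupError):
            find_diagnostic_sites(planted_alignment, planted_panel, "nope")

    def test_lowering_fixedness_never_removes_sites(self, planted_panel,
                                                    planted_alignment):
        strict = {s.column for s in find_diagnostic_sites(
            planted_alignment, planted_panel, "S2",
            SignatureConstraints(fixedness=1.0))}
        loose = {s.column for s in find_diagnostic_sites(
            planted_alignment, planted_panel, "S2",
            SignatureConstraints(fixedness=0.7))}
        assert strict <= loose


class TestExtractSignature:
    def test_published_sequence_recovered_from_constructed_panel(self):
        """A panel whose target carries the published 30-mer at 100..130,
        with backgrounds differing at its two terminal SNPs, yields exactly the
        published signature."""
        rng = np.random.default_rng(8)
        flank = "".join("ACGT"[i] for i in rng.integers(0, 4, 100))
        tail = "".join("ACGT"[i] for i in rng.integers(0, 4, 70))
        target_seq = flank + CY_SIGNATURE + tail
        # background differs at the first and last signature positions
        bg = list(target_seq)
        bg[100] = "G" if bg[100] != "G" else "T"
        bg[129] = "A" if bg[129] != "A" else "C"
        bg_seq = "".join(bg)
        panel, aln = _panel_from_rows(
            [("cy1", "Cynomorium songaricum", target_seq),
             ("cy2", "Cynomorium songaricum", target_seq),
             ("cd1", "Cistanche deserticola", bg_seq),
             ("cd2", "Cistanche deserticola", bg_seq)]
        )
        c = SignatureConstraints(l_min=30, l_max=40, min_sites=2)
        sites = find_diagnostic_sites(aln, panel, "Cynomorium songaricum", c)
        assert {s.column for s in sites} == {100, 129}
        sig = extract_signature(aln, panel, "Cynomorium songaricum", sites, c)
        assert sig.seq == CY_SIGNATURE
        assert (sig.start, sig.end) == (100, 130)
        assert sig.site_offsets == (0, 29)

    def test_single_site_window_has_min_length(self):
        base = "ACGT" * 25
        tgt = base[:50] + "A" + base[51:]
        bkg = base[:50] + "C" + base[51:]
        panel, aln = _panel_from_rows([("t", "T", tgt), ("b", "B", bkg)])
        sites = find_diagnostic_sites(aln, panel, "T")
        sig = extract_signature(aln, panel, "T", sites)
        assert len(sig) == SignatureConstraints().l_min
        assert 50 in {sig.start + o for o in sig.site_offsets}

    def test_matches_exhaustive_window_enumeration(self, planted_panel,
                                                   planted_alignment):
        """Returned (start, length) equals a brute-force scan over all
        admissible windows, shortest first, leftmost first."""
        c = SignatureConstraints(l_min=30, l_max=40, min_sites=1)
        sites = find_diagnostic_sites(planted_alignment, planted_panel, "S2", c)
        sig = extract_signature(planted_alignment, planted_panel, "S2", sites, c)

        ref = planted_panel.records_for("S2")[0].seq
        site_pos = sorted(s.column for s in sites)  # ungapped == columns here
        non_target = [r.seq for r in planted_panel.records if r.species != "S2"]
        found = None
        for L in range(c.l_min, c.l_max + 1):
            for start in range(len(ref) - L + 1):
                window = ref[start : start + L]
                n_inside = sum(start <= p < start + L for p in site_pos)
                if n_inside < c.min_sites:
                    continue
                if any(window in seq for seq in non_target):
                    continue
                found = (start, L)
                break
            if found:
                break
        assert found == (sig.start, len(sig))

    def test_no_sites_raises(self, planted_panel, planted_alignment):
        with pytest.raises(DiscoveryError):
            extract_signature(planted_alignment, planted_panel, "S2", [])

    def test_raising_lmax_never_loses_signature(self, planted_panel,
                                                planted_alignment):
        c1 = SignatureConstraints(l_min=30, l_max=32)
        c2 = SignatureConstraints(l_min=30, l_max=40)
        sites = find_diagnostic_sites(planted_alignment, planted_panel, "S2", c1)
        s1 = extract_signature(planted_alignment, planted_panel, "S2", sites, c1)
        s2 = extract_signature(planted_alignment, planted_panel, "S2", sites, c2)
        assert (s2.start, len(s2)) == (s1.start, len(s1))


class TestVerifyUniqueness:
    def _sig(self, seq, species="T", start=0):
        return NucleotideSignature(
            species=species, seq=seq, ref_record="t1",
            start=start, end=start + len(seq), site_offsets=(len(seq) // 2,),
        )

    def test_verbatim_copy_in_background_detected(self):
        rng = np.random.default_rng(12)
        sig_seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 30))
        bkg = "".join("ACGT"[i] for i in rng.integers(0, 4, 60)) + sig_seq
        panel = ReferencePanel(records=[
            SeqRecord("t1", sig_seq + "ACGTACGT", species="T"),
            SeqRecord("b1", bkg, species="B"),
        ])
        unique, offenders = verify_uniqueness(self._sig(sig_seq), panel)
        assert not unique
        assert len(offenders) == 1 and offenders[0].identity == 100.0

    def test_target_only_panel_is_unique(self):
        rng = np.random.default_rng(13)
        sig_seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 30))
        panel = ReferencePanel(records=[
            SeqRecord("t1", sig_seq, species="T"),
            SeqRecord("t2", sig_seq, species="T"),
        ])
        unique, offenders = verify_uniqueness(self._sig(sig_seq), panel)
        assert unique and offenders == []

    def test_one_mismatch_copy_identity_threshold(self):
        """A 29/30 copy passes at max_ident=1.0 but fails at 0.96."""
        rng = np.random.default_rng(14)
        sig_seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 30))
        near = list(sig_seq)
        near[15] = "ACGT"[("ACGT".index(near[15]) + 1) % 4]
        bkg = "".join("ACGT"[i] for i in rng.integers(0, 4, 40)) + "".join(near)
        panel = ReferencePanel(records=[
            SeqRecord("t1", sig_seq + "AACCGGTT", species="T"),
            SeqRecord("b1", bkg, species="B"),
        ])
        sig = self._sig(sig_seq)
        assert verify_uniqueness(sig, panel, max_ident=1.0)[0] is True
        unique, offenders = verify_uniqueness(sig, panel, max_ident=0.96)
        assert unique is False
        assert offenders[0].identity == pytest.approx(100 * 29 / 30)


class TestInvariants:
    def test_signature_contained_in_reference(self, planted_panel,
                                              planted_alignment):
        sites = find_diagnostic_sites(planted_alignment, planted_panel, "S2")
        sig = extract_signature(planted_alignment, planted_panel, "S2", sites)
        ref = planted_panel.records_for("S2")[0].seq
        assert ref[sig.start : sig.end] == sig.seq
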