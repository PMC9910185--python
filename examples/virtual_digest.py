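"""Virtual gel: amplify and digest each synthetic reference, lane by lane.

Generates the default reference panel (one cytb and one 18S amplicon per
taxon), runs the HinfI / PauI digestions and prints the fragments alongside
the bands that would be visible on a 2% agarose gel.  The visible-band
patterns are the diagnostic profiles of the assay: a single 280 bp cytb band
marks American-eel (or saltwater-eel) mtDNA, 117+164 marks Japanese eel,
an uncut 350 marks European eel; a cut 18S (167+245) marks an American-eel
nuclear background.
"""

from eelid import amplify, default_config, digest, make_reference_panel

cfg = default_config()
panel = make_reference_panel(run_config=cfg)

print(f"{'taxon':<14}{'marker':<8}{'fragments (bp)':<20}visible bands (bp)")
for ref in sorted(panel, key=lambda r: (r.marker.value, r.taxon)):
    amp = amplify(ref, cfg.primer_for(ref.marker))
    res = digest(
        amp,
        cfg.enzyme_for(ref.marker),
        visibility_threshold=cfg.visibility_threshold,
    )
    frags = "+".join(str(f) for f in res.fragments)
    bands = ", ".join(str(b) for b in res.visible_bands)
    print(f"{ref.taxon:<14}{ref.marker.value:<8}{frags:<20}{bands}")
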