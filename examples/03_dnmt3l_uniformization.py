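"""DNMT3L stimulation: strongest at the weakest sites, flattening patterns.

Runs the same planted DNMT3A-like simulation with and without a DNMT3L
saturation boost (p' = 1 - (1-p)^k).  The +DNMT3L run is given a weaker boost
on dcm+ molecules ("old", poorly chromatinized strands), reproducing the
dcm-stratified stimulation readout with its one-tailed t-test.
"""

import warnings

import cpgflank as cf

warnings.filterwarnings("ignore", category=UserWarning)

region = cf.generate_reference(500, 0.6, 40, seed=10)
model = cf.build_preference_model("3A-like", strength=1.0)
common = dict(n_molecules=150, maintenance_efficiency=0.0, conversion_rate=0.991)

alone, _ = cf.simulate_molecules(
    region, model, cf.SimulationParams(seed=11, **common))
with3l, _ = cf.simulate_molecules(
    region, model,
    cf.SimulationParams(seed=12, dnmt3l_exponent=4.0,
                        dnmt3l_exponent_dcm_plus=1.3, **common))

m_alone = cf.call_clones([(m.fasta_header, m.read) for m in alone], region)
m_3l = cf.call_clones([(m.fasta_header, m.read) for m in with3l], region)

t_alone = cf.site_efficiencies(m_alone, strand="top")
t_3l = cf.site_efficiencies(m_3l, strand="top")
stim = cf.fold_stimulation(t_alone, t_3l)

# the inverse relation: low-baseline sites gain the largest fold boost
print(f"fold stimulation vs baseline efficiency: Spearman rho = "
      f"{stim.attrs['trend_rho']:.2f} (p = {stim.attrs['trend_pvalue']:.1e})")
print(f"fold range across sites: {stim.attrs['fold_range_before']:.1f} without "
      f"DNMT3L -> {stim.attrs['fold_range_after']:.1f} with DNMT3L "
      f"(more uniform pattern)")

# rank conservation: DNMT3L boosts efficiency without reshuffling the hierarchy
r, r2 = cf.rank_correlation(t_alone, t_3l)
print(f"site-rank agreement with vs without DNMT3L: r^2 = {r2:.2f}")

for dcm_class in ("dcm-", "dcm+"):
    test = cf.group_stimulation_test(
        cf.molecule_efficiencies(m_alone, dcm_class=dcm_class),
        cf.molecule_efficiencies(m_3l, dcm_class=dcm_class),
    )
    fold = test["mean_3l"] / test["mean_alone"]
    print(f"{dcm_class} strands: {100 * test['mean_alone']:.1f}% -> "
          f"{100 * test['mean_3l']:.1f}% ({fold:.1f}-fold), one-tailed t-test "
          f"p = {test['pvalue']:.2e} [{test['stars']}]")
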