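# Abbreviations whose trailing period never ends a sentence.
# One entry per line, matched case-sensitively at word boundaries.
al.
approx.
ca.
cf.
Co.
Corp.
Dept.
Dr.
Drs.
e.g.
ed.
eds.
Eq.
Eqs.
et al.
etc.
Fig.
Figs.
i.e.
Inc.
Jr.
Ltd.
Mr.
Mrs.
Ms.
No.
Nos.
Ph.D.
Prof.
Ref.
Refs.
resp.
Sec.
Sr.
St.
Suppl.
Tab.
Univ.
viz.
Viz.
vol.
Vol.
vols.
Vols.
vs.
Vs.
Cf.
E.g.
I.e.
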