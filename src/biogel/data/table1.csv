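# Literature observations of spontaneous particle penetration into bio-gels.
# Columns: diameters of penetrating particles (nm), liquid volume fraction cl,
# repeat-unit length l (nm), and the local coordinations m to evaluate.
# Ranges are written lo;hi and default to their midpoint on characterization.
# Mucus: cl = 95%, l in 16-20 nm (midpoint 18 nm used for reported n).
# Biofilms: only ranges are published (cl 87-99%, l 0.07-1.5 nm); the n values
# quoted in the source literature imply an unstated point value near
# J^(1/3)*l ~ 1.2 nm, so biofilm n estimates from midpoints are indicative only.
name,d_min_nm,d_max_nm,d_avg_nm,cl,l_nm,m_values
Respiratory mucus,60,300,140,0.95,18,3;4
Intestinal mucus,20,500,210,0.95,18,3;4
Cervicovaginal mucus,50,1800,340,0.95,18,3;4
Pseudomonas fluorescens biofilm,10,50,30,0.87;0.99,0.07;1.5,3;4
Streptococcus mutans biofilm,0.2,2.5,2.0,0.87;0.99,0.07;1.5,3;4
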