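key	value	units	description
it_tc.m_vhalf	-59.0	mV	T-current (TC variant) activation half-voltage
it_tc.m_slope	6.2	mV	T-current (TC) activation slope
it_tc.h_vhalf	-83.0	mV	T-current (TC) inactivation half-voltage
it_tc.h_slope	-4.0	mV	T-current (TC) inactivation slope (negative: closes with depolarisation)
it_tc.phi_m	3.0	1	temperature factor dividing tau_m (Q10-derived, nominal 36 C)
it_tc.phi_h	3.0	1	temperature factor dividing tau_h
it_re.m_vhalf	-52.0	mV	T-current (RE variant) activation half-voltage
it_re.m_slope	7.4	mV	T-current (RE) activation slope
it_re.h_vhalf	-80.0	mV	T-current (RE) inactivation half-voltage
it_re.h_slope	-5.0	mV	T-current (RE) inactivation slope
it_re.phi_m	3.0	1	temperature factor dividing tau_m
it_re.phi_h	3.0	1	temperature factor dividing tau_h
ih.h_vhalf	-75.0	mV	I_h voltage gate half-activation
ih.h_slope	-5.5	mV	I_h voltage gate slope (activates with hyperpolarisation)
ih.k2	0.0004	1/ms	calcium unbinding rate (P1 -> P0)
ih.cac	0.002	mM	calcium half-binding concentration; k1 = k2 / cac^4
ih.k4	0.001	1/ms	unlocking rate (OL -> O)
ih.pc	0.01	1	half-locking P1; k3 = k4 / pc
ih.ginc	2.0	1	conductance gain of the locked-open state
ih.e_rev	-40.0	mV	I_h reversal potential
ca.rest_mM	0.00024	mM	resting intracellular calcium (thalamic shell)
ca.tau_ms	5.0	ms	calcium pool decay time constant
ca.influx	5.18e-5	mM*cm^2/(ms*uA)	influx factor for a 1 um shell (10/(2*F*d))
ca.out_mM	2.0	mM	extracellular calcium (Nernst E_Ca)
ca.temp_K	309.15	K	temperature for the calcium Nernst potential
km.q	2.95	1	Q10 factor multiplying I_Km rates (2.3^((36-23)/10))
km.rate	0.001	1/(ms*mV)	I_Km alpha/beta rate coefficient
km.vhalf	-30.0	mV	I_Km rate half-voltage
km.vslope	9.0	mV	I_Km rate slope
kca.q	2.95	1	Q10 factor multiplying I_KCa rates
kca.alpha_per_mM	20.0	1/(ms*mM)	I_KCa forward rate per mM calcium
kca.beta	0.03	1/ms	I_KCa backward rate
nap.vhalf	-42.0	mV	persistent sodium activation half-voltage
nap.slope	5.0	mV	persistent sodium activation slope
nap.tau_ms	0.2	ms	persistent sodium activation time constant
hva.q	2.95	1	Q10 factor multiplying I_HVA rates
ca_cortex.rest_mM	5e-5	mM	resting intracellular calcium (cortical dendrite)
ca_cortex.tau_ms	150.0	ms	cortical calcium decay; slow, so Ca accumulates over an Up state
ca_cortex.influx	5e-5	mM*cm^2/(ms*uA)	cortical calcium influx factor
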