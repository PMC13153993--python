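name,arm,base,low,high,family,units,kind
p_init_first_cycle,start,57.3,39.7,65.0,pert,pct_per_30d,probability
p_init_first_cycle,usual_care,26.7,19.8,33.6,pert,pct_per_30d,probability
p_initiated_to_sustained,start,71.4,60.6,82.3,uniform,pct_per_30d,probability
p_initiated_to_sustained,usual_care,70.8,51.2,90.4,uniform,pct_per_30d,probability
p_sustained_stay,start,54.9,46.7,63.2,uniform,pct_per_30d,probability
p_sustained_stay,usual_care,54.3,46.1,62.4,uniform,pct_per_30d,probability
p_death_untreated,shared,0.41,0.29,0.52,beta,pct_per_30d,probability
p_death_initiated,shared,0.12,0.02,0.22,beta,pct_per_30d,probability
p_death_sustained,shared,0.05,0.04,0.05,beta,pct_per_30d,probability
utility_untreated,shared,0.047,0.044,0.050,beta,qaly_per_month,utility
utility_initiated,shared,0.054,0.051,0.057,beta,qaly_per_month,utility
utility_sustained,shared,0.064,0.061,0.066,beta,qaly_per_month,utility
cost_untreated,shared,4184,2092,6276,gamma,usd_per_month,cost
cost_initiated,shared,4149,2075,6224,gamma,usd_per_month,cost
cost_sustained,shared,2886,1443,4329,gamma,usd_per_month,cost
patient_time_cost,shared,115,58,173,gamma,usd_per_month,cost
transportation_cost,shared,55,27,82,gamma,usd_per_month,cost
absenteeism_untreated,shared,50,25,74,gamma,usd_per_month,cost
absenteeism_treated,shared,7,4,11,gamma,usd_per_month,cost
mortality_lost_earnings,shared,4756,2378,7134,gamma,usd_per_month,cost
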