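role,site,activity,hours,hourly_wage
trainer,all,training,15,165.75
AMS,1,training,5,133.24
AMS,2,training,5,209.08
AMS,3,training,5,154.93
CM,1,training,5,82.59
CM,2,training,5,89.00
CM,3,training,5,88.12
AMS,all,delivery,1.73,165.75
AMS,1,delivery,1.66,133.24
AMS,2,delivery,2.25,209.08
AMS,3,delivery,1.58,154.93
CM,all,delivery,3.64,86.57
CM,1,delivery,2.60,82.59
CM,2,delivery,4.72,89.00
CM,3,delivery,3.54,88.12
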