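year,inpt_surge,inpt_nonsurge,pu_los,pu_beds,pr_beds
2009,4182,3496,7.5,23046,4022
2010,4355,3640,7.5,23263,3946
2011,4469,3735,7.2,23286,4098
2012,4523,3780,7.5,23378,4033
2013,4438,3710,7.4,23686,3882
2014,4569,3819,7.3,23891,3906
2015,4627,3867,7.2,24161,4014
2016,4838,4044,7.1,24392,4226
2017,4893,4090,7.2,24621,4644
2018,4874,4074,7.2,25155,4657
2019,4720,3945,7.5,25661,5056
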