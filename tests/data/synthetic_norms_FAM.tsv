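# dimension=FAM
# synthetic fixture ratings for testing; NOT the published norms
answer	6.35	1	7
apple	6.7	1	7
ball	6.3	1	7
belief	5.3	1	7
bird	6.2	1	7
book	6.6	1	7
bread	6.4	1	7
car	6.8	1	7
cat	6.7	1	7
chair	6.4	1	7
chance	5.8	1	7
city	6.5	1	7
concept	4.9	1	7
cup	6.5	1	7
dog	6.9	1	7
egg	6.3	1	7
essence	4.2	1	7
faith	5.1	1	7
family	6.85	1	7
fish	6.25	1	7
flower	6.1	1	7
freedom	5.6	1	7
friend	6.9	1	7
game	6.6	1	7
garden	5.9	1	7
honor	4.9	1	7
hope	5.9	1	7
house	6.85	1	7
idea	6	1	7
journey	5.3	1	7
justice	5.2	1	7
letter	6	1	7
logic	4.8	1	7
luck	5.9	1	7
market	5.8	1	7
meaning	5.5	1	7
moment	6	1	7
morning	6.8	1	7
mountain	5.7	1	7
music	6.7	1	7
principle	4.6	1	7
problem	6.1	1	7
question	6.4	1	7
reason	5.9	1	7
responsibility	5.4	1	7
river	5.9	1	7
school	6.75	1	7
shoe	6.3	1	7
spirit	5.2	1	7
stone	5.6	1	7
story	6.3	1	7
table	6.55	1	7
theory	4.8	1	7
tree	6.45	1	7
truth	5.8	1	7
virtue	3.9	1	7
water	6.95	1	7
window	6.2	1	7
wisdom	4.7	1	7
work	6.8	1	7
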