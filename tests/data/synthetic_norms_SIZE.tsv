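# dimension=SIZE
# synthetic fixture ratings for testing; NOT the published norms
answer	3.7	1	7
apple	2.7	1	7
ball	3	1	7
belief	4.4	1	7
bird	3	1	7
book	3.9	1	7
bread	3.2	1	7
car	5.2	1	7
cat	3.8	1	7
chair	4.2	1	7
chance	3.8	1	7
city	6.5	1	7
concept	4.2	1	7
cup	2.8	1	7
dog	4	1	7
egg	2.03	1	7
essence	3.9	1	7
faith	4.9	1	7
family	5.1	1	7
fish	3.1	1	7
flower	2.6	1	7
freedom	5.7	1	7
friend	4.1	1	7
garden	5	1	7
honor	4.6	1	7
hope	4.9	1	7
house	5.8	1	7
idea	4	1	7
journey	5.4	1	7
justice	5.5	1	7
letter	3.4	1	7
logic	3.9	1	7
luck	3.6	1	7
market	5.4	1	7
meaning	4.1	1	7
moment	2.9	1	7
morning	4.8	1	7
mountain	6.8	1	7
music	4.5	1	7
principle	4.3	1	7
problem	4.4	1	7
question	3.9	1	7
reason	3.8	1	7
responsibility	5.3	1	7
river	6.2	1	7
school	5.6	1	7
shoe	3.1	1	7
spirit	5.1	1	7
stone	2.9	1	7
story	4.3	1	7
table	4.4	1	7
theory	4.8	1	7
tree	5.5	1	7
truth	5.2	1	7
virtue	4.1	1	7
water	5.9	1	7
window	3.8	1	7
wisdom	5	1	7
work	4.7	1	7
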